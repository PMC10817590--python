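"""End-to-end orchestration: simulate -> project -> extract -> analyse.

``run_all`` executes every stage from a single :class:`RunConfig`, writes
all tabular artifacts plus a JSON report, and is byte-deterministic under a
fixed seed.  A failure in any stage leaves a ``FAILED`` marker naming the
stage next to whatever partial outputs exist.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
import matplotlib
import numpy as np
import pandas as pd

from . import __version__
from .cohort import generate_cohort
from .config import RunConfig, config_hash
from .constants import SEXES
from .io import write_dataset
from .stats import GroupAnalysis, run_group_analysis
from .synth import generate_cohort_volumes
from .texture import extract_features

logger = logging.getLogger("oculotex")

_STATE_COLORS = {
    "correlated-out": (0.82, 0.82, 0.82),
    "non-significant": (1.0, 1.0, 1.0),
    "significant-uncorrected": (1.00, 0.78, 0.35),
    "significant-corrected": (0.82, 0.22, 0.18),
}


@dataclass
class RunReport:
    """Summary of one pipeline run (JSON-serialisable)."""

    config_hash: str
    seed: int
    version: str
    group_counts: dict
    files: list

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "version": self.version,
            "group_counts": self.group_counts,
            "files": self.files,
        }


def _stage(name: str, out_dir: Path):
    """Context manager logging stage timing and dropping a FAILED marker on
    error."""
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                logger.info("stage %s: done in %.2fs", name, dt)
                return False
            (out_dir / "FAILED").write_text(f"stage: {name}\nerror: {exc}\n")
            logger.error("stage %s: FAILED after %.2fs: %s", name, dt, exc)
            return False

    return _Ctx()


def analyse_features(features: pd.DataFrame, config: RunConfig
                     ) -> dict[str, GroupAnalysis]:
    return {group: run_group_analysis(features, group, config.stats)
            for group in SEXES}


def run_all(config: RunConfig, out_dir) -> RunReport:
    """Run the whole pipeline and write artifacts under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    files: list[str] = []

    with _stage("simulate", out):
        cohort = generate_cohort(config.cohort)
        pd.DataFrame([vars(p) for p in cohort]).to_csv(out / "cohort.csv",
                                                       index=False)
        files.append("cohort.csv")
        scans = generate_cohort_volumes(cohort, config.volume, config.effects,
                                        seed=config.seed)
        if config.write_volumes:
            scans = list(scans)
            write_dataset(cohort, scans, out / "dataset")
            files.append("dataset/manifest.json")

    with _stage("extract", out):
        features = extract_features(scans, layers=config.layers,
                                    config=config.glcm)
        features.to_csv(out / "features.csv", index=False)
        files.append("features.csv")

    group_counts = {}
    with _stage("analyse", out):
        analyses = analyse_features(features, config)
        for group, ga in analyses.items():
            ga.selection.frame().to_csv(out / f"selection_{group}.csv", index=False)
            ga.tests.to_csv(out / f"tests_{group}.csv", index=False)
            for method, res in ga.corrections.items():
                pd.DataFrame({
                    "feature": ga.selection.kept,
                    "p": ga.tests["p"],
                    "adjusted": res.adjusted,
                    "significant": res.significant,
                }).to_csv(out / f"correction_{method}_{group}.csv", index=False)
                files.append(f"correction_{method}_{group}.csv")
            write_grid_tsv(ga.grid, out / f"grid_{group}.tsv")
            files.extend([f"selection_{group}.csv", f"tests_{group}.csv",
                          f"grid_{group}.tsv"])
            group_counts[group] = ga.counts

    report = RunReport(config_hash=chash, seed=config.seed,
                       version=__version__, group_counts=group_counts,
                       files=sorted(files))
    with _stage("report", out):
        with open(out / "report.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=1)
        (out / "summary.txt").write_text(format_summary(report))
    return report


def format_summary(report: RunReport) -> str:
    lines = [
        f"oculotex {report.version}  config {report.config_hash}  seed {report.seed}",
        "",
        f"{'group':<8} {'features':>8} {'kept':>5} {'p<a':>5} "
        f"{'bonf':>5} {'bh':>5} {'storey':>7} {'pi0':>6} {'FDR@t':>7}",
    ]
    for group, c in report.group_counts.items():
        lines.append(
            f"{group:<8} {c['n_features']:>8} {c['n_uncorrelated']:>5} "
            f"{c['uncorrected_significant']:>5} {c['bonferroni']:>5} "
            f"{c['benjamini_hochberg']:>5} {c['storey']:>7} "
            f"{c['storey_pi0']:>6.2f} {c['storey_fdr_estimate']:>7.3f}"
        )
    return "\n".join(lines) + "\n"


def write_grid_tsv(grid: pd.DataFrame, path) -> None:
    """State grid as TSV with layer/quadrant column headers (lossless
    round-trip via :func:`read_grid_tsv`)."""
    flat = grid.copy()
    flat.columns = [f"{l}/{q}" for l, q in grid.columns]
    flat.to_csv(path, sep="\t", index_label="feature")


def read_grid_tsv(path) -> pd.DataFrame:
    flat = pd.read_csv(path, sep="\t", index_col="feature")
    flat.columns = pd.MultiIndex.from_tuples(
        [tuple(c.split("/", 1)) for c in flat.columns])
    return flat


def render_grid(grid: pd.DataFrame, out_png, out_tsv=None) -> None:
    """Render the feature x (layer, quadrant) state grid as an image
    (corrected-significant dark red, uncorrected orange, correlated-out
    grey, non-significant white) and optionally as TSV."""
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Patch

    rgb = np.ones(grid.shape + (3,))
    for i in range(grid.shape[0]):
        for j in range(grid.shape[1]):
            state = str(grid.iloc[i, j]).split(":")[0]
            rgb[i, j] = _STATE_COLORS.get(state, (1.0, 1.0, 1.0))
    fig, ax = plt.subplots(
        figsize=(0.45 * grid.shape[1] + 3, 0.3 * grid.shape[0] + 2))
    ax.imshow(rgb, aspect="auto")
    ax.set_xticks(range(grid.shape[1]))
    ax.set_xticklabels([f"{l}\n{q}" for l, q in grid.columns], fontsize=7)
    ax.set_yticks(range(grid.shape[0]))
    ax.set_yticklabels(grid.index, fontsize=7)
    ax.set_xticks(np.arange(-0.5, grid.shape[1]), minor=True)
    ax.set_yticks(np.arange(-0.5, grid.shape[0]), minor=True)
    ax.grid(which="minor", color="0.6", linewidth=0.4)
    ax.tick_params(which="both", length=0)
    ax.legend(handles=[Patch(facecolor=c, edgecolor="0.5", label=s)
                       for s, c in _STATE_COLORS.items()],
              loc="upper left", bbox_to_anchor=(1.01, 1.0), fontsize=7)
    fig.tight_layout()
    fig.savefig(out_png, dpi=150)
    plt.close(fig)
    if out_tsv is not None:
        write_grid_tsv(grid, out_tsv)
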