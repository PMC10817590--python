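"""Interocular paired-asymmetry statistics.

For each sex group: (1) Pearson-correlate every feature with every other
feature of the same eye; pairs with |r| >= 0.5 in *both* eyes are correlated
and pruned down to a pairwise-uncorrelated subset, (2) each kept feature is
gated by Shapiro-Wilk normality (10% level, both eyes) into a paired t-test
or a Wilcoxon signed-rank test of right vs left eye, and (3) the resulting
p-values are corrected with Bonferroni, Benjamini-Hochberg and Storey's
q-value / FDR-estimation procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import StatsConfig
from .constants import feature_id, feature_id_sort_key
from .errors import ConfigurationError, DataError


# ---------------------------------------------------------------------------
# Correlation filter
# ---------------------------------------------------------------------------

@dataclass
class CorrelationSet:
    """Pairwise Pearson correlations of a group's features, per eye.

    ``correlated[i, j]`` is True when |r| >= threshold in both eyes.
    Features that are constant in either eye have undefined r and are
    treated as uncorrelated (listed in ``undefined``).
    """

    feature_ids: list[str]
    r_od: np.ndarray
    r_os: np.ndarray
    correlated: np.ndarray
    threshold: float
    undefined: list[str] = field(default_factory=list)

    def records(self, correlated_only: bool = True) -> pd.DataFrame:
        """Tidy pair table (feature_a, feature_b, r_od, r_os, correlated)."""
        iu = np.triu_indices(len(self.feature_ids), k=1)
        keep = self.correlated[iu] if correlated_only else np.ones(len(iu[0]), bool)
        ids = np.asarray(self.feature_ids, dtype=object)
        return pd.DataFrame({
            "feature_a": ids[iu[0][keep]],
            "feature_b": ids[iu[1][keep]],
            "r_od": self.r_od[iu][keep],
            "r_os": self.r_os[iu][keep],
            "correlated": self.correlated[iu][keep],
        })


def pairwise_correlations(od: pd.DataFrame, os_: pd.DataFrame,
                          threshold: float = 0.5) -> CorrelationSet:
    """Correlate every feature with every other, separately per eye.

    ``od`` and ``os_`` are participants x features matrices with identical
    row/column order (one row per participant of the group).
    """
    if list(od.columns) != list(os_.columns) or list(od.index) != list(os_.index):
        raise DataError("OD and OS matrices must share participants and features")
    if len(od) < 3:
        raise DataError("need at least 3 participants for correlations")
    for name, frame in (("OD", od), ("OS", os_)):
        if frame.isna().any().any():
            bad = frame.columns[frame.isna().any()].tolist()
            raise DataError(f"missing values in {name} features: {bad[:5]}")
    ids = list(od.columns)
    with np.errstate(invalid="ignore", divide="ignore"):
        r_od = np.corrcoef(od.to_numpy(dtype=float), rowvar=False)
        r_os = np.corrcoef(os_.to_numpy(dtype=float), rowvar=False)
    undef = np.isnan(r_od) | np.isnan(r_os)
    correlated = (np.abs(r_od) >= threshold) & (np.abs(r_os) >= threshold)
    correlated &= ~undef
    np.fill_diagonal(correlated, False)
    constant = (od.std(ddof=0) == 0) | (os_.std(ddof=0) == 0)
    return CorrelationSet(feature_ids=ids, r_od=r_od, r_os=r_os,
                          correlated=correlated, threshold=threshold,
                          undefined=list(od.columns[constant]))


@dataclass
class SelectionResult:
    """Outcome of the decorrelation pass."""

    kept: list[str]
    discarded: dict[str, str]  # feature -> keeper that removed it
    n_correlations: dict[str, int]
    ev_sum: dict[str, float]  # sum of r_od^2 + r_os^2 over correlated partners

    def frame(self) -> pd.DataFrame:
        rows = []
        for fid in self.kept:
            rows.append({"feature": fid, "status": "kept", "removed_by": "",
                         "n_correlations": self.n_correlations[fid],
                         "ev_sum": self.ev_sum[fid]})
        for fid, keeper in self.discarded.items():
            rows.append({"feature": fid, "status": "discarded",
                         "removed_by": keeper,
                         "n_correlations": self.n_correlations[fid],
                         "ev_sum": self.ev_sum[fid]})
        return pd.DataFrame(rows)


def select_uncorrelated(corr: CorrelationSet,
                        recompute_after_discard: bool = False) -> SelectionResult:
    """Prune the feature set until all pairwise |r| < threshold in both eyes.

    Features in no correlated pair are kept outright.  The remaining
    features are ranked by decreasing number of correlated partners (n),
    ties broken by decreasing explained-variance sum (sum of
    r_od^2 + r_os^2 over partners), then by canonical feature order.  The
    ranked list is traversed once, keeping each not-yet-discarded feature
    and discarding its remaining correlated partners; with
    ``recompute_after_discard`` the ranking is instead recomputed among the
    undecided features after every keep.
    """
    A = corr.correlated
    ids = corr.feature_ids
    m = len(ids)
    ev_matrix = np.where(A, np.nan_to_num(corr.r_od) ** 2
                         + np.nan_to_num(corr.r_os) ** 2, 0.0)
    n_corr = A.sum(axis=1)
    ev = ev_matrix.sum(axis=1)
    order_key = {fid: i for i, fid in enumerate(sorted(ids, key=feature_id_sort_key))}

    STATUS_UNDECIDED, STATUS_KEPT, STATUS_DISCARDED = 0, 1, -1
    status = np.zeros(m, dtype=int)
    discarded_by: dict[str, str] = {}

    involved = np.flatnonzero(n_corr > 0)
    if not recompute_after_discard:
        ranking = sorted(involved,
                         key=lambda i: (-n_corr[i], -ev[i], order_key[ids[i]]))
        for i in ranking:
            if status[i] == STATUS_DISCARDED:
                continue
            status[i] = STATUS_KEPT
            for j in np.flatnonzero(A[i]):
                if status[j] == STATUS_UNDECIDED:
                    status[j] = STATUS_DISCARDED
                    discarded_by[ids[j]] = ids[i]
    else:
        while True:
            undecided = np.flatnonzero((status == STATUS_UNDECIDED) & (n_corr > 0))
            sub = [i for i in undecided if A[i][status == STATUS_UNDECIDED].any()]
            if not sub:
                break
            live = status == STATUS_UNDECIDED
            n_live = A[:, live].sum(axis=1)
            ev_live = ev_matrix[:, live].sum(axis=1)
            best = min(sub, key=lambda i: (-n_live[i], -ev_live[i], order_key[ids[i]]))
            status[best] = STATUS_KEPT
            for j in np.flatnonzero(A[best]):
                if status[j] == STATUS_UNDECIDED:
                    status[j] = STATUS_DISCARDED
                    discarded_by[ids[j]] = ids[best]

    kept = [ids[i] for i in range(m) if status[i] != STATUS_DISCARDED]
    kept_idx = [i for i in range(m) if status[i] != STATUS_DISCARDED]
    if A[np.ix_(kept_idx, kept_idx)].any():
        raise AssertionError("selection left a correlated pair in the kept set")
    return SelectionResult(
        kept=kept,
        discarded=discarded_by,
        n_correlations={fid: int(n_corr[i]) for i, fid in enumerate(ids)},
        ev_sum={fid: float(ev[i]) for i, fid in enumerate(ids)},
    )


# ---------------------------------------------------------------------------
# Normality gate and paired tests
# ---------------------------------------------------------------------------

def normality_gate(od: np.ndarray, os_: np.ndarray,
                   level: float = 0.10) -> tuple[bool, bool]:
    """Shapiro-Wilk on each eye's sample; normal iff p >= level.

    The 10% level is deliberately conservative: it diverts borderline
    samples to the non-parametric test.
    """
    od, os_ = np.asarray(od, float), np.asarray(os_, float)
    if len(od) < 3 or len(os_) < 3:
        raise DataError("Shapiro-Wilk needs at least 3 observations per eye")

    def sw_normal(x):
        if np.ptp(x) == 0:
            return False  # constant sample: not plausibly normal
        return bool(sps.shapiro(x).pvalue >= level)

    return sw_normal(od), sw_normal(os_)


@dataclass
class PairedTestResult:
    feature: str
    normal_od: bool
    normal_os: bool
    test: str  # "paired-t" or "wilcoxon"
    statistic: float
    p: float
    degenerate: bool = False


def _wilcoxon(diff: np.ndarray) -> tuple[float, float]:
    """Wilcoxon signed-rank dialect: drop zero differences, average tied
    ranks, exact null distribution for n <= 25 tie-free samples, otherwise a
    continuity-corrected normal approximation."""
    nz = diff[diff != 0]
    n = len(nz)
    ties = len(np.unique(np.abs(nz))) < n
    method = "exact" if (n <= 25 and not ties) else "approx"
    res = sps.wilcoxon(nz, zero_method="wilcox", correction=True,
                       alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def paired_test(od: np.ndarray, os_: np.ndarray, gate: tuple[bool, bool],
                feature: str = "") -> PairedTestResult:
    """Two-sided paired OD-vs-OS test, parametric iff both eyes pass the
    normality gate.  Identical samples are flagged degenerate with p = 1."""
    od, os_ = np.asarray(od, float), np.asarray(os_, float)
    if od.shape != os_.shape:
        raise DataError("paired samples must have equal length")
    normal_od, normal_os = gate
    diff = od - os_
    if np.all(diff == 0):
        return PairedTestResult(feature, normal_od, normal_os,
                                "paired-t" if normal_od and normal_os else "wilcoxon",
                                statistic=0.0, p=1.0, degenerate=True)
    if normal_od and normal_os:
        res = sps.ttest_rel(od, os_)
        return PairedTestResult(feature, normal_od, normal_os, "paired-t",
                                float(res.statistic), float(res.pvalue))
    stat, p = _wilcoxon(diff)
    return PairedTestResult(feature, normal_od, normal_os, "wilcoxon", stat, p)


# ---------------------------------------------------------------------------
# Multiple-comparison corrections
# ---------------------------------------------------------------------------

@dataclass
class CorrectionResult:
    method: str
    alpha: float
    m: int
    significant: np.ndarray  # boolean, aligned with the input p-values
    adjusted: np.ndarray  # adjusted p / q-values, aligned with the input
    pi0: Optional[float] = None
    fdr_estimate: Optional[float] = None
    lam: Optional[float] = None


def _check_pvals(pvals) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or len(p) < 1:
        raise DataError("need a 1-D array of at least one p-value")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DataError("p-values must lie in [0, 1]")
    return p


def bonferroni(pvals, alpha: float = 0.05) -> CorrectionResult:
    """Family-wise control: significant iff p < alpha / m."""
    p = _check_pvals(pvals)
    m = len(p)
    return CorrectionResult("bonferroni", alpha, m,
                            significant=p < alpha / m,
                            adjusted=np.minimum(1.0, m * p))


def benjamini_hochberg(pvals, alpha: float = 0.05) -> CorrectionResult:
    """Step-up FDR control: find the largest k with p_(k) < k * alpha / m and
    declare the k smallest p-values significant; adjusted values are the
    usual monotone step-up transform capped at 1."""
    p = _check_pvals(pvals)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1)
    sorted_p = p[order]
    passing = sorted_p < ranks * alpha / m
    k = int(ranks[passing].max()) if passing.any() else 0
    significant = np.zeros(m, dtype=bool)
    significant[order[:k]] = True
    adj_sorted = np.minimum.accumulate((m * sorted_p / ranks)[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adj_sorted, 1.0)
    return CorrectionResult("benjamini_hochberg", alpha, m,
                            significant=significant, adjusted=adjusted)


def storey(pvals, alpha: float = 0.05, lam: float = 0.5,
           t: float = 0.05) -> CorrectionResult:
    """Storey's FDR: estimate the null proportion pi0 = #{p > lambda} /
    (m (1 - lambda)) (capped at 1), the FDR at threshold ``t``, and q-values
    q(p_(i)) = min_{j >= i} pi0 * m * p_(j) / j; significant iff q < alpha.
    With lambda = 0 the q-values coincide with Benjamini-Hochberg adjusted
    p-values."""
    if not (0 <= lam < 1):
        raise ConfigurationError("lambda must be in [0, 1)")
    p = _check_pvals(pvals)
    m = len(p)
    pi0 = min(1.0, np.sum(p > lam) / (m * (1.0 - lam)))
    fdr_t = min(1.0, pi0 * m * t / max(int(np.sum(p <= t)), 1))
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate((pi0 * m * p[order] / ranks)[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return CorrectionResult("storey", alpha, m, significant=q < alpha,
                            adjusted=q, pi0=float(pi0),
                            fdr_estimate=float(fdr_t), lam=lam)


CORRECTION_METHODS = ("bonferroni", "benjamini_hochberg", "storey")


# ---------------------------------------------------------------------------
# Group-level orchestration
# ---------------------------------------------------------------------------

@dataclass
class GroupAnalysis:
    group: str
    feature_ids: list[str]
    correlations: CorrelationSet
    selection: SelectionResult
    tests: pd.DataFrame
    corrections: dict[str, CorrectionResult]
    grid: pd.DataFrame  # features x (layer, quadrant) state strings
    counts: dict


def eye_matrices(features: pd.DataFrame, group: str) -> dict[str, pd.DataFrame]:
    """Pivot a tidy feature table into per-eye participants x features
    matrices with canonically ordered, aligned rows and columns."""
    sub = features[features["sex"] == group]
    if sub.empty:
        raise DataError(f"no rows for group {group!r}")
    sub = sub.assign(
        fid=[feature_id(l, q, f) for l, q, f in
             zip(sub["layer"], sub["quadrant"], sub["feature"])]
    )
    mats = {}
    for eye in ("OD", "OS"):
        wide = sub[sub["eye"] == eye].pivot(index="participant_id",
                                            columns="fid", values="value")
        wide = wide[sorted(wide.columns, key=feature_id_sort_key)]
        mats[eye] = wide.sort_index()
    if list(mats["OD"].index) != list(mats["OS"].index):
        raise DataError("participants are not paired across eyes")
    return mats


GRID_STATES = ("correlated-out", "non-significant", "significant-uncorrected",
               "significant-corrected")


def run_group_analysis(features: pd.DataFrame, group: str,
                       config: Optional[StatsConfig] = None) -> GroupAnalysis:
    """Full statistical pipeline for one sex group.

    Returns the correlation filter outcome, per-feature paired tests on the
    uncorrelated subset, the three corrections (with m = number of kept
    features), a per-feature state grid and a count summary.
    """
    config = config or StatsConfig()
    mats = eye_matrices(features, group)
    od, os_ = mats["OD"], mats["OS"]
    ids = list(od.columns)

    corr = pairwise_correlations(od, os_, threshold=config.r_threshold)
    selection = select_uncorrelated(
        corr, recompute_after_discard=config.recompute_after_discard)

    test_rows = []
    for fid in selection.kept:
        x, y = od[fid].to_numpy(), os_[fid].to_numpy()
        if config.normality_on == "differences":
            d = x - y
            normal = normality_gate(d, d, level=config.sw_level)[0]
            gate = (normal, normal)
        else:
            gate = normality_gate(x, y, level=config.sw_level)
        res = paired_test(x, y, gate, feature=fid)
        test_rows.append({
            "feature": fid, "normal_od": res.normal_od,
            "normal_os": res.normal_os, "test": res.test,
            "statistic": res.statistic, "p": res.p,
            "degenerate": res.degenerate,
        })
    tests = pd.DataFrame(test_rows)
    p = tests["p"].to_numpy()

    corrections = {
        "bonferroni": bonferroni(p, alpha=config.alpha),
        "benjamini_hochberg": benjamini_hochberg(p, alpha=config.alpha),
        "storey": storey(p, alpha=config.alpha, lam=config.storey_lambda,
                         t=config.storey_t),
    }

    sig_methods: dict[str, list[str]] = {fid: [] for fid in selection.kept}
    for method, res in corrections.items():
        for fid, is_sig in zip(selection.kept, res.significant):
            if is_sig:
                sig_methods[fid].append(method)

    kept_p = dict(zip(selection.kept, p))
    layers = list(dict.fromkeys(features["layer"]))
    quads = list(dict.fromkeys(features["quadrant"]))
    feats = list(dict.fromkeys(features["feature"]))
    grid = pd.DataFrame(index=feats,
                        columns=pd.MultiIndex.from_product([layers, quads]),
                        dtype=object)
    for fid in ids:
        layer, quadrant, name = fid.split("/", 2)
        if fid in selection.discarded:
            state = "correlated-out"
        elif sig_methods.get(fid):
            state = "significant-corrected:" + "+".join(sig_methods[fid])
        elif kept_p[fid] < config.alpha:
            state = "significant-uncorrected"
        else:
            state = "non-significant"
        grid.loc[name, (layer, quadrant)] = state

    n_kept = len(selection.kept)
    counts = {
        "group": group,
        "n_features": len(ids),
        "n_uncorrelated": n_kept,
        "n_nonparametric": int((tests["test"] == "wilcoxon").sum()),
        "uncorrected_significant": int((p < config.alpha).sum()),
        "bonferroni": int(corrections["bonferroni"].significant.sum()),
        "benjamini_hochberg": int(corrections["benjamini_hochberg"].significant.sum()),
        "storey": int(corrections["storey"].significant.sum()),
        "storey_pi0": corrections["storey"].pi0,
        "storey_fdr_estimate": corrections["storey"].fdr_estimate,
    }
    return GroupAnalysis(group=group, feature_ids=ids, correlations=corr,
                         selection=selection, tests=tests,
                         corrections=corrections, grid=grid, counts=counts)
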