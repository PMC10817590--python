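"""On-disk dataset formats.

A dataset directory holds one multi-page TIFF per eye scan (one page per
B-scan, rows = depth, columns = A-scans), one interface CSV per scan
(columns: bscan, ascan, z_0..z_6), a cohort CSV and a JSON manifest listing
every scan with its participant and eye.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import tifffile

from .cohort import ParticipantRecord
from .constants import LAYERS
from .errors import DataError
from .projection import LayerInterfaces, OCTVolume

MANIFEST_NAME = "manifest.json"

_Z_COLS = [f"z_{k}" for k in range(len(LAYERS) + 1)]


def write_volume_tiff(path, volume: OCTVolume) -> None:
    """Write a volume as a multi-page float32 TIFF: page = B-scan, each page
    depth x A-scans (lossless round-trip)."""
    tifffile.imwrite(path, volume.intensity.astype(np.float32),
                     photometric="minisblack")


def read_volume_tiff(path, eye: str, participant_id: str) -> OCTVolume:
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    return OCTVolume(intensity=np.asarray(data, dtype=np.float32),
                     eye=eye, participant_id=participant_id)


def write_interfaces_csv(path, interfaces: LayerInterfaces) -> None:
    _, nb, na = interfaces.z.shape
    bb, aa = np.meshgrid(np.arange(nb), np.arange(na), indexing="ij")
    table = {"bscan": bb.ravel(), "ascan": aa.ravel()}
    for k, col in enumerate(_Z_COLS):
        table[col] = interfaces.z[k].ravel()
    pd.DataFrame(table).to_csv(path, index=False)


def read_interfaces_csv(path) -> LayerInterfaces:
    df = pd.read_csv(path)
    nb = int(df["bscan"].max()) + 1
    na = int(df["ascan"].max()) + 1
    if len(df) != nb * na:
        raise DataError(f"interface table {path} has an incomplete grid")
    df = df.sort_values(["bscan", "ascan"])
    z = np.stack([df[col].to_numpy().reshape(nb, na) for col in _Z_COLS])
    return LayerInterfaces(z=z)


def write_dataset(cohort: Sequence[ParticipantRecord], scans: Iterable,
                  out_dir) -> dict:
    """Write a full dataset and return (and save) its manifest.

    ``scans`` iterates (participant, eye, volume, interfaces) tuples, e.g.
    from :func:`oculotex.synth.generate_cohort_volumes`.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise DataError(f"cannot create output directory {out}: {exc}") from exc

    pd.DataFrame([vars(p) for p in cohort]).to_csv(out / "cohort.csv", index=False)
    entries = []
    for participant, eye, volume, interfaces in scans:
        stem = f"{participant.participant_id}_{eye}"
        vol_name, ifc_name = f"{stem}.tiff", f"{stem}_interfaces.csv"
        write_volume_tiff(out / vol_name, volume)
        write_interfaces_csv(out / ifc_name, interfaces)
        entries.append({
            "participant_id": participant.participant_id,
            "sex": participant.sex,
            "age": participant.age,
            "eye": eye,
            "volume": vol_name,
            "interfaces": ifc_name,
        })
    manifest = {"cohort": "cohort.csv", "scans": entries}
    with open(out / MANIFEST_NAME, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def load_dataset(manifest_path) -> Iterator[tuple]:
    """Yield (participant, eye, volume, interfaces) for every scan listed in
    a dataset manifest; missing files raise an error naming them all."""
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / MANIFEST_NAME
    base = manifest_path.parent
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    missing = [e[key] for e in manifest["scans"] for key in ("volume", "interfaces")
               if not (base / e[key]).exists()]
    if missing:
        raise DataError(f"dataset is missing files: {missing}")
    for entry in manifest["scans"]:
        participant = ParticipantRecord(entry["participant_id"], entry["sex"],
                                        float(entry["age"]))
        volume = read_volume_tiff(base / entry["volume"], entry["eye"],
                                  entry["participant_id"])
        interfaces = read_interfaces_csv(base / entry["interfaces"])
        yield participant, entry["eye"], volume, interfaces
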