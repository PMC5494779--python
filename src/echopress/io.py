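"""Plain-text storage for A-line records and feature/impedance tables.

Each A-line is one two-column CSV (sample_index, amplitude) and a dataset
is a directory of such files plus a JSON manifest recording dt, pressure,
identifiers and SHA-256 checksums, so any dataset is regenerable and
verifiable bit for bit from its config and seed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import ALineRecord

__all__ = [
    "write_aline_dataset",
    "read_aline_dataset",
    "write_table",
    "read_table",
]

MANIFEST_NAME = "manifest.json"
# 9 significant digits keeps files compact while round-tripping well below
# the noise floor (float64 written/read through text).
_FLOAT_FMT = "%.9g"


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _record_filename(rec: ALineRecord) -> str:
    iop = "ref" if np.isnan(rec.iop) else f"{rec.iop:g}"
    return f"aline_iop{iop}_{rec.eye_id}_r{rec.repeat_id}_a{rec.aline_id}.csv"


def write_aline_dataset(records: list[ALineRecord], out_dir: str | Path) -> Path:
    """Write records as CSVs plus a manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in records:
        fname = _record_filename(rec)
        fpath = out_dir / fname
        with fpath.open("w") as fh:
            fh.write("sample_index,amplitude\n")
            for i, v in enumerate(rec.samples):
                fh.write(f"{i},{_FLOAT_FMT % v}\n")
        entries.append(
            {
                "file": fname,
                "sha256": _sha256(fpath),
                "dt": rec.dt,
                "iop": None if np.isnan(rec.iop) else rec.iop,
                "eye_id": rec.eye_id,
                "repeat_id": rec.repeat_id,
                "aline_id": rec.aline_id,
                "n_samples": int(rec.samples.size),
            }
        )
    manifest = {"format": "echopress-aline-v1", "records": entries}
    mpath = out_dir / MANIFEST_NAME
    mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return mpath


def read_aline_dataset(in_dir: str | Path, verify: bool = True) -> list[ALineRecord]:
    """Read a dataset back from its manifest, optionally verifying checksums."""
    in_dir = Path(in_dir)
    mpath = in_dir / MANIFEST_NAME
    if not mpath.exists():
        raise FileNotFoundError(f"no {MANIFEST_NAME} in {in_dir}")
    manifest = json.loads(mpath.read_text())
    records = []
    for entry in manifest["records"]:
        fpath = in_dir / entry["file"]
        if verify and _sha256(fpath) != entry["sha256"]:
            raise IOError(f"checksum mismatch for {fpath}")
        df = pd.read_csv(fpath)
        records.append(
            ALineRecord(
                samples=df["amplitude"].to_numpy(),
                dt=entry["dt"],
                iop=float("nan") if entry["iop"] is None else entry["iop"],
                eye_id=entry["eye_id"],
                repeat_id=entry["repeat_id"],
                aline_id=entry["aline_id"],
            )
        )
    return records


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a feature/impedance table as CSV with stable float formatting."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.12g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
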