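"""Tabular readers/writers for multiplet data and result tables.

The canonical dialect is TSV (UTF-8, header row, '.' decimal); CSV is
accepted on read by extension sniffing.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .nmr import MultipletMeasurement, NMRSample

__all__ = [
    "ParseError",
    "REQUIRED_COLUMNS",
    "read_multiplet_table",
    "write_multiplet_table",
    "samples_to_frame",
]

REQUIRED_COLUMNS = (
    "sample_id", "heart_id", "group", "dry_weight_g",
    "glutamate_umol_per_gdw", "multiplet", "intensity", "sigma", "detected",
)


class ParseError(ValueError):
    """Input-table error carrying the offending file line."""


def _read_frame(path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def read_multiplet_table(path) -> list[NMRSample]:
    """Read a tidy multiplet table into per-sample records.

    One row per (sample, multiplet); rows are grouped by ``sample_id``.
    Line numbers in error messages are 1-based file lines (header = line 1).
    """
    df = _read_frame(path)
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    dup = df.duplicated(subset=["sample_id", "multiplet"])
    if dup.any():
        i = int(df.index[dup][0])
        raise ParseError(
            f"{path}: line {i + 2}: duplicate (sample_id, multiplet) pair "
            f"({df.loc[i, 'sample_id']!r}, {df.loc[i, 'multiplet']!r})")
    bad = ~(df["sigma"] > 0)
    if bad.any():
        i = int(df.index[bad][0])
        raise ParseError(
            f"{path}: line {i + 2}: sigma must be > 0 for multiplet "
            f"{df.loc[i, 'multiplet']!r} of sample {df.loc[i, 'sample_id']!r}")
    samples = []
    for sid, g in df.groupby("sample_id", sort=False):
        first = g.iloc[0]
        meas = {}
        for _, row in g.iterrows():
            detected = bool(row["detected"])
            meas[str(row["multiplet"])] = MultipletMeasurement(
                float(row["intensity"]) if detected else 0.0,
                float(row["sigma"]), detected)
        samples.append(NMRSample(
            str(sid), str(first["heart_id"]), str(first["group"]),
            float(first["dry_weight_g"]), float(first["glutamate_umol_per_gdw"]),
            meas))
    return samples


def samples_to_frame(samples: Sequence[NMRSample]) -> pd.DataFrame:
    rows = []
    for s in samples:
        for name, m in s.multiplets.items():
            rows.append({
                "sample_id": s.sample_id, "heart_id": s.heart_id,
                "group": s.group, "dry_weight_g": s.dry_weight_g,
                "glutamate_umol_per_gdw": s.glutamate_conc,
                "multiplet": name, "intensity": m.intensity,
                "sigma": m.sigma, "detected": m.detected,
            })
    return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))


def write_multiplet_table(samples: Sequence[NMRSample], path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    # %.17g keeps the write -> read round trip bit-exact
    samples_to_frame(samples).to_csv(path, sep=sep, index=False,
                                     float_format="%.17g")
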