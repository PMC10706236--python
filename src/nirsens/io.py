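"""CSV/JSON readers and writers for spectra, sensory tables and reports.

CSV dialect is fixed for bit-exact interchange: comma separator, ``.``
decimal, UTF-8, mandatory header row.  Floats are written with ``repr`` so a
write/read cycle round-trips binary64 values exactly.
"""
from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    SCORE_MAX,
    SCORE_MIN,
    SensoryTable,
    SpectraSet,
    ValidationError,
    align,
)

__all__ = [
    "read_spectra",
    "write_spectra",
    "read_sensory",
    "write_sensory",
    "align",
]


def write_spectra(spectra: SpectraSet, path: str | Path) -> None:
    """Write wide CSV: sample_id, replicate, then one column per wavenumber."""
    spectra.to_frame().to_csv(path, index=False, encoding="utf-8")


def read_spectra(path: str | Path) -> SpectraSet:
    """Read a wide spectra CSV and enforce all :class:`SpectraSet` invariants."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    required = {"sample_id", "replicate"}
    if not required.issubset(df.columns):
        raise ValidationError(f"spectra CSV must have columns {sorted(required)}")
    wn_cols = [c for c in df.columns if c not in required]
    try:
        wavenumbers = np.array([float(c) for c in wn_cols])
    except ValueError as exc:
        raise ValidationError(f"non-numeric wavenumber column header: {exc}") from exc
    order = np.argsort(wavenumbers)
    wn_cols = [wn_cols[i] for i in order]
    block = df[wn_cols]
    bad = block.isna() | ~block.map(np.isreal)
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"missing or non-numeric absorbance at row {r} "
            f"(sample {df['sample_id'].iloc[r]}), column {wn_cols[c]}"
        )
    try:
        absorbance = block.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-numeric absorbance value: {exc}") from exc
    return SpectraSet(
        wavenumbers=wavenumbers[order],
        absorbance=absorbance,
        sample_ids=df["sample_id"].astype(str).to_numpy(),
        replicate_ids=df["replicate"].astype(int).to_numpy(),
    )


def write_sensory(sensory: SensoryTable, path: str | Path) -> None:
    """Write sensory CSV: sample_id column followed by attribute columns."""
    df = sensory.scores.copy()
    df.insert(0, "sample_id", df.index)
    df.to_csv(path, index=False, encoding="utf-8", float_format=None)


def read_sensory(path: str | Path, strict: bool = True) -> SensoryTable:
    """Read a sensory CSV.

    Scores outside the [1, 9] scale raise in ``strict`` mode (default); in
    lenient mode they are clipped to the scale bounds with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    if "sample_id" not in df.columns:
        raise ValidationError("sensory CSV must have a sample_id column")
    df = df.set_index(df["sample_id"].astype(str)).drop(columns="sample_id")
    df.index.name = None
    vals = df.to_numpy(dtype=float)
    out_of_range = (vals < SCORE_MIN) | (vals > SCORE_MAX)
    if out_of_range.any():
        r, c = np.argwhere(out_of_range)[0]
        msg = (
            f"score {vals[r, c]} outside [{SCORE_MIN}, {SCORE_MAX}] at sample "
            f"{df.index[r]}, attribute {df.columns[c]}"
        )
        if strict:
            raise ValidationError(msg)
        warnings.warn(msg + "; clipping to scale bounds", stacklevel=2)
        df = df.clip(SCORE_MIN, SCORE_MAX)
    return SensoryTable(scores=df)
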