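"""Core in-memory containers: NIR spectra blocks and sensory score tables.

A :class:`SpectraSet` is the X block at every stage of the pipeline: a matrix of
absorbance rows (one per sample-replicate record) over an ordered wavenumber
axis.  A :class:`SensoryTable` is the Y block: panel scores on the 1-9 intensity
scale for the ten descriptive attributes of a dry-cured loin tasting protocol.
"""
from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Iterable, Literal

import numpy as np
import pandas as pd

#: The ten sensory attributes scored by the trained panel.
ATTRIBUTES: tuple[str, ...] = (
    "Odor",
    "Andros",
    "Scatol",
    "Lean color",
    "Fat color",
    "Hardness",
    "Juiciness",
    "Chewiness",
    "Flavor intensity",
    "Flavor persistence",
)

SCORE_MIN = 1.0
SCORE_MAX = 9.0


class ValidationError(ValueError):
    """Raised when a container or file violates a structural invariant."""


@dataclasses.dataclass
class SpectraSet:
    """Absorbance matrix over a strictly increasing wavenumber axis.

    Parameters
    ----------
    wavenumbers : (n_channels,) array, cm^-1, strictly increasing.
    absorbance : (n_rows, n_channels) array. Rows are sample-replicate records.
    sample_ids : (n_rows,) array of str.
    replicate_ids : (n_rows,) array of int.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    sample_ids: np.ndarray
    replicate_ids: np.ndarray

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        self.sample_ids = np.asarray(self.sample_ids, dtype=str)
        self.replicate_ids = np.asarray(self.replicate_ids, dtype=int)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        if self.wavenumbers.ndim != 1 or self.wavenumbers.size < 1:
            raise ValidationError("wavenumbers must be a non-empty 1-D vector")
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise ValidationError("wavenumbers must be strictly increasing")
        n_rows, n_chan = self.absorbance.shape
        if n_chan != self.wavenumbers.size:
            raise ValidationError(
                f"absorbance has {n_chan} columns but axis has "
                f"{self.wavenumbers.size} wavenumbers"
            )
        if len(self.sample_ids) != n_rows or len(self.replicate_ids) != n_rows:
            raise ValidationError("sample_ids/replicate_ids length != row count")
        if not np.all(np.isfinite(self.absorbance)):
            bad = np.argwhere(~np.isfinite(self.absorbance))[0]
            raise ValidationError(
                f"non-finite absorbance at row {bad[0]} "
                f"(sample {self.sample_ids[bad[0]]}), channel {bad[1]}"
            )
        pairs = list(zip(self.sample_ids.tolist(), self.replicate_ids.tolist()))
        dupes = [p for p, c in Counter(pairs).items() if c > 1]
        if dupes:
            raise ValidationError(f"duplicate (sample, replicate) records: {dupes[:3]}")
        counts = Counter(self.sample_ids.tolist())
        if len(set(counts.values())) > 1:
            raise ValidationError(
                f"unequal replicate counts per sample: {dict(counts)}"
            )

    # -- convenience --------------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_channels(self) -> int:
        return self.absorbance.shape[1]

    @property
    def unique_samples(self) -> list[str]:
        """Sample ids in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.sample_ids.tolist():
            seen.setdefault(s, None)
        return list(seen)

    def with_absorbance(self, absorbance: np.ndarray) -> "SpectraSet":
        """Same identity/axis, new absorbance matrix (e.g. after a transform)."""
        return SpectraSet(
            wavenumbers=self.wavenumbers.copy(),
            absorbance=np.asarray(absorbance, dtype=float),
            sample_ids=self.sample_ids.copy(),
            replicate_ids=self.replicate_ids.copy(),
        )

    def take_rows(self, idx: Iterable[int]) -> "SpectraSet":
        idx = np.asarray(list(idx), dtype=int)
        return SpectraSet(
            wavenumbers=self.wavenumbers.copy(),
            absorbance=self.absorbance[idx],
            sample_ids=self.sample_ids[idx],
            replicate_ids=self.replicate_ids[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.absorbance, columns=[repr(float(w)) for w in self.wavenumbers]
        )
        df.insert(0, "replicate", self.replicate_ids)
        df.insert(0, "sample_id", self.sample_ids)
        return df


@dataclasses.dataclass
class SensoryTable:
    """Per-sample panel scores (1-9 scale) for the ten sensory attributes."""

    scores: pd.DataFrame  # index: sample_id (str), columns: attribute names

    def __post_init__(self) -> None:
        self.scores = self.scores.copy()
        self.scores.index = self.scores.index.astype(str)
        self.validate()

    def validate(self) -> None:
        unknown = [c for c in self.scores.columns if c not in ATTRIBUTES]
        if unknown:
            raise ValidationError(
                f"unknown attribute(s) {unknown}; valid names: {list(ATTRIBUTES)}"
            )
        if self.scores.index.has_duplicates:
            dup = self.scores.index[self.scores.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dup[:3]}")
        vals = self.scores.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            r, c = np.argwhere(~np.isfinite(vals))[0]
            raise ValidationError(
                f"missing/non-numeric score at sample {self.scores.index[r]}, "
                f"attribute {self.scores.columns[c]}"
            )
        if vals.size and (vals.min() < SCORE_MIN or vals.max() > SCORE_MAX):
            r, c = np.argwhere((vals < SCORE_MIN) | (vals > SCORE_MAX))[0]
            raise ValidationError(
                f"score {vals[r, c]} outside [{SCORE_MIN}, {SCORE_MAX}] at sample "
                f"{self.scores.index[r]}, attribute {self.scores.columns[c]}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return self.scores.index.tolist()

    @property
    def attributes(self) -> list[str]:
        return self.scores.columns.tolist()

    def attribute(self, name: str) -> np.ndarray:
        if name not in self.scores.columns:
            raise KeyError(
                f"unknown attribute {name!r}; valid names: {list(self.scores.columns)}"
            )
        return self.scores[name].to_numpy(dtype=float)


@dataclasses.dataclass
class PairedData:
    """X and Y blocks with rows in one-to-one correspondence."""

    spectra: SpectraSet
    sensory: SensoryTable

    def __post_init__(self) -> None:
        ns = self.spectra.n_rows
        if len(self.sensory.scores) != ns:
            raise ValidationError(
                f"paired rows mismatch: {ns} spectra rows vs "
                f"{len(self.sensory.scores)} sensory rows"
            )

    @property
    def n(self) -> int:
        return self.spectra.n_rows


def align(
    spectra: SpectraSet,
    sensory: SensoryTable,
    replicate_policy: Literal["mean", "keep"] = "mean",
) -> PairedData:
    """Pair spectra with sensory scores on sample id.

    ``mean`` (default) averages the replicate spectra of each sample so the
    paired design has one row per sample; ``keep`` repeats each sample's score
    row once per replicate spectrum.  Samples present in only one block are
    dropped; an empty intersection is an error.
    """
    if replicate_policy not in ("mean", "keep"):
        raise ValueError(f"replicate_policy must be 'mean' or 'keep', got {replicate_policy!r}")
    common = [s for s in spectra.unique_samples if s in set(sensory.sample_ids)]
    if not common:
        raise ValidationError("no common sample ids between spectra and sensory table")

    if replicate_policy == "mean":
        rows = []
        for s in common:
            mask = spectra.sample_ids == s
            rows.append(spectra.absorbance[mask].mean(axis=0))
        x = SpectraSet(
            wavenumbers=spectra.wavenumbers,
            absorbance=np.vstack(rows),
            sample_ids=np.array(common),
            replicate_ids=np.zeros(len(common), dtype=int),
        )
        y = SensoryTable(scores=sensory.scores.loc[common])
        return PairedData(spectra=x, sensory=y)

    keep_mask = np.isin(spectra.sample_ids, common)
    idx = np.flatnonzero(keep_mask)
    x = spectra.take_rows(idx)
    expanded = sensory.scores.loc[x.sample_ids.tolist()]
    expanded = expanded.set_axis(
        [f"{s}#r{r}" for s, r in zip(x.sample_ids, x.replicate_ids)], axis=0
    )
    # replicate-expanded Y keeps one row per spectrum; index is sample#replicate
    y = SensoryTable(scores=expanded)
    return PairedData(spectra=x, sensory=y)
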