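"""End-to-end orchestration: grid search over pre-treatment x normalization
x SVR type x kernel, per-attribute SPXY splitting, PSO tuning and reporting.

For each attribute and grid cell the pipeline: smooths and pre-treats all
sample spectra (MSC reference = overall mean, since no split exists yet) to
compute SPXY distances; partitions into calibration (67%) and prediction
(33%) subsets; refits the preprocessing chain on calibration rows only;
tunes the SVR hyperparameters by hybrid PSO + pattern search with 5-fold
RMSECV as the objective; refits the best spec on the full calibration set;
and scores the prediction set.  The best cell per attribute is the one with
the lowest RMSECV (prediction RMSEP breaks ties) — selection never looks at
the prediction set except through the tie-break among RMSECV-equal cells.

Per-cell seeds are derived from the master seed plus the attribute name and
cell coordinates (not their enumeration order), so identical cells receive
identical randomness in any grid and a run manifest reruns bit-identically.
"""
from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .containers import ATTRIBUTES, PairedData, SensoryTable, SpectraSet, align
from .evaluation import MeritReport, merit_report
from .preprocess import (
    NORMALIZATION_METHODS,
    PRETREATMENT_METHODS,
    NormalizationSpec,
    PreprocessChain,
    PreTreatmentSpec,
    apply_pretreatment,
    fit_pretreatment,
    smooth_spline,
)
from .pso import PsoConfig, TuningResult, tune_svr
from .regression import FittedModel, fit_pls, fit_svr
from .selection import SplitResult, spxy

__all__ = [
    "GridCell",
    "GridSpec",
    "RunConfig",
    "RunRecord",
    "GridResult",
    "pso_preset",
    "run_grid",
    "calibrate_cell",
    "write_report",
]

SVR_TYPES = ("epsilon", "nu")
KERNELS = ("linear", "polynomial", "radial_base", "sigmoid")

#: Winning configuration of the emulated study: MSC pre-treatment, MinMax
#: normalization, epsilon-SVR with the radial-base kernel.
BEST_CELL = ("msc", "minmax", "epsilon", "radial_base")


@dataclasses.dataclass(frozen=True)
class GridCell:
    pre_treatment: str
    normalization: str
    svr_type: str
    kernel: str

    def as_tuple(self) -> tuple[str, str, str, str]:
        return (self.pre_treatment, self.normalization, self.svr_type, self.kernel)


@dataclasses.dataclass
class GridSpec:
    """Axes of the model grid; defaults cover the full tested space."""

    pre_treatments: tuple[str, ...] = PRETREATMENT_METHODS
    normalizations: tuple[str, ...] = NORMALIZATION_METHODS
    svr_types: tuple[str, ...] = SVR_TYPES
    kernels: tuple[str, ...] = KERNELS
    attributes: tuple[str, ...] = ATTRIBUTES

    def __post_init__(self) -> None:
        axes = {
            "pre_treatments": (self.pre_treatments, PRETREATMENT_METHODS),
            "normalizations": (self.normalizations, NORMALIZATION_METHODS),
            "svr_types": (self.svr_types, SVR_TYPES),
            "kernels": (self.kernels, KERNELS),
            "attributes": (self.attributes, ATTRIBUTES),
        }
        for name, (values, valid) in axes.items():
            if not values:
                raise ValueError(f"grid axis {name} is empty")
            unknown = [v for v in values if v not in valid]
            if unknown:
                raise ValueError(f"unknown {name} value(s): {unknown}")

    def cells(self) -> list[GridCell]:
        return [
            GridCell(*combo)
            for combo in itertools.product(
                self.pre_treatments, self.normalizations, self.svr_types, self.kernels
            )
        ]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(**{k: tuple(v) for k, v in d.items()})


def pso_preset(name: str) -> PsoConfig:
    """PSO budgets: "full" for full-scale runs, "ci" for desk-scale runs."""
    if name == "full":
        return PsoConfig(swarm_size=20, max_iterations=50, patience=10)
    if name == "ci":
        return PsoConfig(swarm_size=10, max_iterations=20, patience=6, ps_tolerance=1e-3)
    raise ValueError(f"unknown PSO preset {name!r} (use 'full' or 'ci')")


@dataclasses.dataclass
class RunConfig:
    """Reproducibility manifest: everything needed to rerun bit-identically."""

    master_seed: int = 0
    fraction: float = 0.67
    replicate_policy: str = "mean"
    smoothing_param: float = 0.01
    pso_budget: str = "ci"
    cv_folds: int = 5
    selection_metric: str = "rmsecv"  # or "rmsep"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)


def cell_seeds(master_seed: int, attribute: str, cell: GridCell) -> tuple[int, int]:
    """(pso_seed, cv_seed) < 2^31, stable under grid enumeration order."""
    key = f"{master_seed}|{attribute}|{'|'.join(cell.as_tuple())}".encode()
    digest = hashlib.sha256(key).digest()
    pso_seed = int.from_bytes(digest[:4], "big") % 2**31
    cv_seed = int.from_bytes(digest[4:8], "big") % 2**31
    return pso_seed, cv_seed


@dataclasses.dataclass
class RunRecord:
    """Everything produced for one (attribute, cell): reconstructible from seeds."""

    attribute: str
    cell: GridCell
    pso_seed: int
    cv_seed: int
    split: Optional[SplitResult] = None
    tuning: Optional[TuningResult] = None
    merit: Optional[MeritReport] = None
    model: Optional[FittedModel] = None
    error: Optional[str] = None


@dataclasses.dataclass
class GridResult:
    records: list[RunRecord]
    best: pd.DataFrame  # one row per attribute

    def record_for(self, attribute: str, cell: GridCell) -> RunRecord:
        for r in self.records:
            if r.attribute == attribute and r.cell == cell:
                return r
        raise KeyError((attribute, cell))


def _split_for_cell(
    paired: PairedData,
    attribute: str,
    cell: GridCell,
    config: RunConfig,
) -> SplitResult:
    """SPXY split on smoothed + pre-treated X (before normalization) and y."""
    smoothed = smooth_spline(paired.spectra, config.smoothing_param)
    spec = fit_pretreatment(
        smoothed, PreTreatmentSpec(method=cell.pre_treatment, smoothing_param=config.smoothing_param)
    )
    treated = apply_pretreatment(smoothed, spec)
    y = paired.sensory.attribute(attribute)
    return spxy(treated.absorbance, y, fraction=config.fraction)


def calibrate_cell(
    paired: PairedData,
    attribute: str,
    cell: GridCell,
    split: SplitResult,
    config: RunConfig,
    pso_config: Optional[PsoConfig] = None,
) -> tuple[FittedModel, TuningResult]:
    """Fit one grid cell on a given split: chain -> tune -> refit on calibration."""
    pso_seed, cv_seed = cell_seeds(config.master_seed, attribute, cell)
    if pso_config is None:
        pso_config = dataclasses.replace(pso_preset(config.pso_budget), seed=pso_seed)
    chain = PreprocessChain(
        pretreatment=PreTreatmentSpec(method=cell.pre_treatment),
        normalization=NormalizationSpec(method=cell.normalization),
        smoothing_param=config.smoothing_param,
    )
    cal_spectra = paired.spectra.take_rows(split.calibration_idx)
    X_cal = chain.fit_transform(cal_spectra)
    y = paired.sensory.attribute(attribute)
    y_cal = y[split.calibration_idx]
    tuning = tune_svr(
        X_cal,
        y_cal,
        svr_type=cell.svr_type,
        kernel=cell.kernel,
        pso_config=pso_config,
        cv_seed=cv_seed,
        k=min(config.cv_folds, len(y_cal)),
    )
    model = fit_svr(X_cal, y_cal, tuning.best_params)
    model.preprocessor = chain
    return model, tuning


def run_grid(
    spectra: SpectraSet,
    sensory: SensoryTable,
    grid: Optional[GridSpec] = None,
    config: Optional[RunConfig] = None,
) -> GridResult:
    """Run the full grid and emit the best-model-per-attribute table."""
    grid = grid or GridSpec()
    config = config or RunConfig()
    paired = align(spectra, sensory, replicate_policy=config.replicate_policy)
    records: list[RunRecord] = []
    for attribute in grid.attributes:
        for cell in grid.cells():
            pso_seed, cv_seed = cell_seeds(config.master_seed, attribute, cell)
            rec = RunRecord(attribute=attribute, cell=cell, pso_seed=pso_seed, cv_seed=cv_seed)
            try:
                split = _split_for_cell(paired, attribute, cell, config)
                model, tuning = calibrate_cell(paired, attribute, cell, split, config)
                y = paired.sensory.attribute(attribute)
                rec.split = split
                rec.tuning = tuning
                rec.model = model
                rec.merit = merit_report(
                    model, paired.spectra, y, split, attribute=attribute
                )
            except Exception as exc:  # record and continue with other cells
                rec.error = f"{type(exc).__name__}: {exc}"
            records.append(rec)
    best = _best_table(records, grid, config)
    return GridResult(records=records, best=best)


def _best_table(records: list[RunRecord], grid: GridSpec, config: RunConfig) -> pd.DataFrame:
    rows = []
    for attribute in grid.attributes:
        ok = [r for r in records if r.attribute == attribute and r.error is None]
        if not ok:
            errs = {r.cell.as_tuple(): r.error for r in records if r.attribute == attribute}
            raise RuntimeError(f"every grid cell failed for attribute {attribute!r}: {errs}")
        if config.selection_metric == "rmsep":
            key = lambda r: (r.merit.rmsep, r.tuning.best_rmsecv)  # noqa: E731
        else:
            key = lambda r: (r.tuning.best_rmsecv, r.merit.rmsep)  # noqa: E731
        best = min(ok, key=key)
        spec = best.tuning.best_params
        rows.append(
            {
                "attribute": attribute,
                "pre_treatment": best.cell.pre_treatment,
                "normalization": best.cell.normalization,
                "svr_type": best.cell.svr_type,
                "kernel": best.cell.kernel,
                "C": spec.C,
                "epsilon": spec.epsilon,
                "nu": spec.nu,
                "gamma": spec.gamma,
                "coef0": spec.coef0,
                "degree": spec.degree,
                "RMSECV": best.tuning.best_rmsecv,
                "RMSEC": best.merit.rmsec,
                "R2_cal": best.merit.r2_cal,
                "RMSEP": best.merit.rmsep,
                "R2_pred": best.merit.r2_pred,
                "RSD_pct": best.merit.rsd_pred_pct,
                "EJCR_contains_ideal": best.merit.ejcr_contains_ideal,
                "DW": best.merit.dw_statistic,
                "pDW": best.merit.dw_probability,
            }
        )
    return pd.DataFrame(rows)


def write_report(best: pd.DataFrame, path: str | Path) -> None:
    """Write the best-per-attribute table as CSV (full float precision)."""
    cols = best.copy()
    for c in cols.columns:
        if cols[c].dtype == float:
            cols[c] = cols[c].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    cols.to_csv(path, index=False, encoding="utf-8")


def pls_baseline(
    paired: PairedData,
    attribute: str,
    split: SplitResult,
    cell: GridCell,
    config: RunConfig,
) -> tuple[FittedModel, MeritReport]:
    """PLS model on the same split and preprocessing as an SVR cell."""
    _, cv_seed = cell_seeds(config.master_seed, attribute, cell)
    chain = PreprocessChain(
        pretreatment=PreTreatmentSpec(method=cell.pre_treatment),
        normalization=NormalizationSpec(method=cell.normalization),
        smoothing_param=config.smoothing_param,
    )
    cal_spectra = paired.spectra.take_rows(split.calibration_idx)
    X_cal = chain.fit_transform(cal_spectra)
    y = paired.sensory.attribute(attribute)
    model = fit_pls(X_cal, y[split.calibration_idx], cv_seed=cv_seed)
    model.preprocessor = chain
    merit = merit_report(model, paired.spectra, y, split, attribute=attribute)
    return model, merit


def save_run(result: GridResult, config: RunConfig, grid: GridSpec, out_dir: str | Path) -> None:
    """Persist a run: manifest, per-cell splits/trajectories, report.csv."""
    out = Path(out_dir)
    (out / "splits").mkdir(parents=True, exist_ok=True)
    (out / "trajectories").mkdir(exist_ok=True)
    (out / "models").mkdir(exist_ok=True)
    manifest = {"config": config.to_dict(), "grid": grid.to_dict()}
    (out / "config.json").write_text(json.dumps(manifest, indent=1), encoding="utf-8")
    for rec in result.records:
        stem = f"{rec.attribute.replace(' ', '_')}__{'_'.join(rec.cell.as_tuple())}"
        if rec.split is not None:
            rec.split.save(out / "splits" / f"{stem}.json")
        if rec.tuning is not None:
            np.savetxt(
                out / "trajectories" / f"{stem}.csv",
                rec.tuning.trajectory,
                header="best_rmsecv",
                comments="",
                delimiter=",",
            )
        if rec.model is not None:
            (out / "models" / f"{stem}.json").write_text(rec.model.to_json(), encoding="utf-8")
    write_report(result.best, out / "report.csv")
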