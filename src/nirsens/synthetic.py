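"""Synthetic paired NIR spectra + sensory scores for dry-cured loin.

The generator emulates the measurement design the pipeline assumes: 40 minced
loin samples, each scanned three times on a 4000-10,000 cm^-1 grid at 4 cm^-1
resolution, paired with panel scores (1-9 scale) for ten sensory attributes.

Each sample has a latent composition (protein/lipid/water fractions on the
simplex plus a drying index).  Spectra are sums of constituent Gaussian
absorption bands placed at the classical C-H / N-H / O-H overtone and
combination wavelengths, corrupted per replicate by multiplicative gain,
additive offset (scatter) and i.i.d. instrument noise.  Sensory scores are
monotone, mildly nonlinear functions of the latents plus noise, affinely
rescaled to configurable per-attribute (mean, sd) targets and clipped to the
bounded 1-9 scale.  The ground-truth functional form is exposed via
:func:`sensory_signal` for parameter-recovery experiments.
"""
from __future__ import annotations

import dataclasses
import json
import warnings

import numpy as np
import pandas as pd

from .containers import ATTRIBUTES, SCORE_MAX, SCORE_MIN, SensoryTable, SpectraSet

__all__ = [
    "Band",
    "AttributeTarget",
    "GeneratorConfig",
    "LatentComposition",
    "generate_latents",
    "generate_spectra",
    "generate_sensory",
    "generate_dataset",
    "sensory_signal",
]


@dataclasses.dataclass(frozen=True)
class Band:
    """One Gaussian absorption band, specified in wavelength (nm).

    ``drying_coupled`` marks bands whose amplitude shrinks with the drying
    index (free-water loss during curing); the shape itself is Gaussian in
    wavenumber space.
    """

    center_nm: float
    width_nm: float
    amplitude: float
    drying_coupled: bool = False


@dataclasses.dataclass(frozen=True)
class AttributeTarget:
    """Target marginal statistics (min, max, mean, sd) for one attribute."""

    min: float
    max: float
    mean: float
    sd: float

    def validate(self, name: str) -> None:
        if not (self.min < self.mean < self.max):
            raise ValueError(f"attribute {name!r}: require min < mean < max")
        if self.sd < 0:
            raise ValueError(f"attribute {name!r}: sd must be >= 0")


#: Marginal score statistics of the forty-loin panel study (min, max, mean, sd).
DEFAULT_ATTRIBUTE_TARGETS: dict[str, AttributeTarget] = {
    "Odor": AttributeTarget(5.13, 6.78, 5.92, 0.38),
    "Andros": AttributeTarget(1.11, 2.38, 1.50, 0.28),
    "Scatol": AttributeTarget(1.00, 1.78, 1.24, 0.19),
    "Lean color": AttributeTarget(2.88, 6.11, 4.05, 0.73),
    "Fat color": AttributeTarget(1.56, 4.89, 3.11, 0.85),
    "Hardness": AttributeTarget(2.44, 6.56, 3.90, 1.23),
    "Juiciness": AttributeTarget(3.44, 6.11, 5.10, 0.64),
    "Chewiness": AttributeTarget(2.13, 5.44, 3.62, 0.85),
    "Flavor intensity": AttributeTarget(5.11, 6.44, 5.89, 0.33),
    "Flavor persistence": AttributeTarget(4.56, 6.33, 5.67, 0.42),
}

#: Constituent band assignments: C-H near 1200, 1710-1760 and 2300-2350 nm
#: (overtones + combination), N-H and O-H in the 1450 and 1900 nm regions.
DEFAULT_BANDS: dict[str, tuple[Band, ...]] = {
    "protein": (
        Band(1190.0, 40.0, 0.25),
        Band(1450.0, 55.0, 0.35),
        Band(2300.0, 60.0, 0.45),
    ),
    "lipid": (
        Band(1210.0, 35.0, 0.40),
        Band(1725.0, 45.0, 0.60),
        Band(1760.0, 45.0, 0.45),
        Band(2310.0, 55.0, 0.50),
        Band(2350.0, 55.0, 0.40),
    ),
    "water": (
        Band(1450.0, 60.0, 0.50),
        Band(1900.0, 70.0, 0.90, drying_coupled=True),
    ),
}

#: Loadings of each attribute on (protein, lipid, water, drying) latents.
#: Signs encode plausible monotone directions (e.g. hardness rises with
#: protein and drying, falls with water); magnitudes are normalized at use.
ATTRIBUTE_LOADINGS: dict[str, tuple[float, float, float, float]] = {
    "Odor": (0.2, 0.4, -0.2, 0.8),
    "Andros": (0.1, 0.9, 0.0, 0.3),
    "Scatol": (0.0, 0.8, 0.2, 0.4),
    "Lean color": (0.6, 0.1, -0.5, 0.6),
    "Fat color": (0.1, 0.7, -0.3, 0.5),
    "Hardness": (0.7, -0.2, -0.6, 0.5),
    "Juiciness": (-0.4, 0.3, 0.8, -0.4),
    "Chewiness": (0.7, -0.1, -0.5, 0.4),
    "Flavor intensity": (0.3, 0.5, -0.3, 0.7),
    "Flavor persistence": (0.3, 0.4, -0.2, 0.8),
}


@dataclasses.dataclass
class LatentComposition:
    """Latent drivers of one sample: composition simplex + drying index."""

    sample_id: str
    protein_frac: float
    lipid_frac: float
    water_frac: float
    drying_index: float

    def __post_init__(self) -> None:
        s = self.protein_frac + self.lipid_frac + self.water_frac
        if min(self.protein_frac, self.lipid_frac, self.water_frac) <= 0:
            raise ValueError("constituent fractions must be positive")
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1 (got {s!r})")
        if not 0.0 <= self.drying_index <= 1.0:
            raise ValueError("drying_index must lie in [0, 1]")

    def as_vector(self) -> np.ndarray:
        return np.array(
            [self.protein_frac, self.lipid_frac, self.water_frac, self.drying_index]
        )


@dataclasses.dataclass
class GeneratorConfig:
    """Study-design and noise parameters of the synthetic generator.

    Defaults reproduce the measurement geometry of the emulated study: 40
    samples, 3 replicate scans, 4000-10,000 cm^-1 at 4 cm^-1 steps, and the
    published per-attribute score statistics as rescaling targets.
    """

    n_samples: int = 40
    n_replicates: int = 3
    wavenumber_start: float = 4000.0
    wavenumber_stop: float = 10000.0
    wavenumber_step: float = 4.0
    bands: dict[str, tuple[Band, ...]] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )
    # composition prior: Dirichlet concentration ~ 60 x typical dry-cured loin
    # proximate composition (38% protein, 13% lipid, 49% moisture)
    dirichlet_alpha: tuple[float, float, float] = (22.8, 7.8, 29.4)
    drying_beta: tuple[float, float] = (2.0, 2.0)
    drying_water_coupling: float = 0.5
    baseline_level: float = 0.3
    scatter_gain_sd: float = 0.05
    scatter_offset_sd: float = 0.01
    noise_sd: float = 1e-3
    nonlinearity: float = 1.0
    sensory_noise_sd: float = 0.1
    attribute_targets: dict[str, AttributeTarget] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_ATTRIBUTE_TARGETS)
    )
    seed: int = 0

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        if self.n_samples < 4:
            raise ValueError(
                "n_samples must be >= 4 (subset selection and cross-validation "
                "downstream need at least 4 samples)"
            )
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.wavenumber_step <= 0:
            raise ValueError("wavenumber_step must be > 0")
        if self.wavenumber_stop <= self.wavenumber_start:
            raise ValueError("wavenumber_stop must exceed wavenumber_start")
        for name in ("scatter_gain_sd", "scatter_offset_sd", "noise_sd", "sensory_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        unknown = [a for a in self.attribute_targets if a not in ATTRIBUTES]
        if unknown:
            raise ValueError(
                f"unknown attribute name(s) {unknown}; valid names: {list(ATTRIBUTES)}"
            )
        for name, tgt in self.attribute_targets.items():
            tgt.validate(name)

    # -- axis ---------------------------------------------------------------
    def wavenumber_grid(self) -> np.ndarray:
        n = int(round((self.wavenumber_stop - self.wavenumber_start) / self.wavenumber_step)) + 1
        return self.wavenumber_start + self.wavenumber_step * np.arange(n)

    # -- JSON round-trip ----------------------------------------------------
    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["bands"] = {k: [dataclasses.asdict(b) for b in v] for k, v in self.bands.items()}
        d["attribute_targets"] = {
            k: dataclasses.asdict(t) for k, t in self.attribute_targets.items()
        }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GeneratorConfig":
        d = json.loads(text)
        d["bands"] = {
            k: tuple(Band(**b) for b in v) for k, v in d.get("bands", {}).items()
        }
        d["attribute_targets"] = {
            k: AttributeTarget(**t) for k, t in d.get("attribute_targets", {}).items()
        }
        d["dirichlet_alpha"] = tuple(d["dirichlet_alpha"])
        d["drying_beta"] = tuple(d["drying_beta"])
        return cls(**d)


def _streams(config: GeneratorConfig) -> tuple[np.random.Generator, ...]:
    """Independent child RNGs for the three generation stages."""
    children = np.random.SeedSequence(config.seed).spawn(3)
    return tuple(np.random.default_rng(c) for c in children)


def generate_latents(config: GeneratorConfig) -> list[LatentComposition]:
    """Draw per-sample latent compositions.

    Fractions are sampled from a Dirichlet distribution on the protein /
    lipid / water simplex; the drying index from a Beta distribution.
    Deterministic for a fixed ``config.seed``.
    """
    config.validate()
    rng, _, _ = _streams(config)
    fracs = rng.dirichlet(np.asarray(config.dirichlet_alpha, dtype=float), size=config.n_samples)
    drying = rng.beta(*config.drying_beta, size=config.n_samples)
    return [
        LatentComposition(
            sample_id=f"S{i + 1:03d}",
            protein_frac=float(fracs[i, 0]),
            lipid_frac=float(fracs[i, 1]),
            water_frac=float(fracs[i, 2]),
            drying_index=float(drying[i]),
        )
        for i in range(config.n_samples)
    ]


def _pure_spectrum(latent: LatentComposition, config: GeneratorConfig, grid: np.ndarray) -> np.ndarray:
    """Noise-free absorbance: sum of constituent-weighted Gaussian bands."""
    nm_lo = 1e7 / grid[-1]
    nm_hi = 1e7 / grid[0]
    fracs = {
        "protein": latent.protein_frac,
        "lipid": latent.lipid_frac,
        "water": latent.water_frac,
    }
    # broad diffuse-reflectance baseline keeps absorbance strictly positive
    spec = np.full_like(grid, config.baseline_level)
    for constituent, bands in config.bands.items():
        frac = fracs.get(constituent, 0.0)
        for band in bands:
            if not (nm_lo <= band.center_nm <= nm_hi):
                warnings.warn(
                    f"band at {band.center_nm} nm lies outside the "
                    f"[{nm_lo:.0f}, {nm_hi:.0f}] nm grid; skipped",
                    stacklevel=3,
                )
                continue
            center_wn = 1e7 / band.center_nm
            sigma_wn = band.width_nm * 1e7 / band.center_nm**2
            amp = band.amplitude
            if band.drying_coupled:
                amp *= 1.0 - config.drying_water_coupling * latent.drying_index
            spec += frac * amp * np.exp(-0.5 * ((grid - center_wn) / sigma_wn) ** 2)
    return spec


def generate_spectra(latents: list[LatentComposition], config: GeneratorConfig) -> SpectraSet:
    """Replicate spectra: pure constituent bands + scatter + instrument noise.

    Per replicate row: ``gain * pure + offset + noise`` with gain ~ N(1,
    scatter_gain_sd), offset ~ N(0, scatter_offset_sd) and i.i.d. channel
    noise ~ N(0, noise_sd).  Gain and offset vary per replicate so scatter
    correction has real work to do.
    """
    if not latents:
        raise ValueError("latents must be non-empty")
    config.validate()
    _, rng, _ = _streams(config)
    grid = config.wavenumber_grid()
    rows, sample_ids, replicate_ids = [], [], []
    for latent in latents:
        pure = _pure_spectrum(latent, config, grid)
        for rep in range(config.n_replicates):
            gain = 1.0 + rng.normal(0.0, config.scatter_gain_sd) if config.scatter_gain_sd else 1.0
            offset = rng.normal(0.0, config.scatter_offset_sd) if config.scatter_offset_sd else 0.0
            noise = (
                rng.normal(0.0, config.noise_sd, size=grid.size)
                if config.noise_sd
                else 0.0
            )
            rows.append(gain * pure + offset + noise)
            sample_ids.append(latent.sample_id)
            replicate_ids.append(rep)
    return SpectraSet(
        wavenumbers=grid,
        absorbance=np.vstack(rows),
        sample_ids=np.array(sample_ids),
        replicate_ids=np.array(replicate_ids),
    )


def sensory_signal(latents: list[LatentComposition], config: GeneratorConfig) -> pd.DataFrame:
    """Noise-free latent signal per attribute, before rescaling.

    For each attribute, z is the unit-norm loading combination of the
    empirically standardized latents and the signal is the monotone map
    ``z + nonlinearity * z**3 / 3``.  This is the retained ground truth that
    parameter-recovery experiments compare against.
    """
    lat = np.vstack([l.as_vector() for l in latents])
    sd = lat.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    z_lat = (lat - lat.mean(axis=0)) / sd
    out = {}
    for name in config.attribute_targets:
        c = np.asarray(ATTRIBUTE_LOADINGS[name], dtype=float)
        c = c / np.linalg.norm(c)
        z = z_lat @ c
        out[name] = z + config.nonlinearity * z**3 / 3.0
    return pd.DataFrame(out, index=[l.sample_id for l in latents])


def generate_sensory(latents: list[LatentComposition], config: GeneratorConfig) -> SensoryTable:
    """Panel scores: latent signal + noise, rescaled to target (mean, sd).

    Gaussian noise with sd ``sensory_noise_sd`` (in standardized signal
    units) is added to the latent signal; the noisy signal is then affinely
    rescaled to the configured per-attribute mean and sd and clipped to the
    bounded [1, 9] scale.
    """
    if not latents:
        raise ValueError("latents must be non-empty")
    config.validate()
    _, _, rng = _streams(config)
    signal = sensory_signal(latents, config)
    cols = {}
    for name, tgt in config.attribute_targets.items():
        f = signal[name].to_numpy()
        noisy = f + rng.normal(0.0, config.sensory_noise_sd, size=f.size)
        s = noisy.std(ddof=1)
        scaled = tgt.mean + tgt.sd * (noisy - noisy.mean()) / (s if s > 0 else 1.0)
        cols[name] = np.clip(scaled, SCORE_MIN, SCORE_MAX)
    return SensoryTable(scores=pd.DataFrame(cols, index=signal.index))


def generate_dataset(config: GeneratorConfig) -> tuple[SpectraSet, SensoryTable, list[LatentComposition]]:
    """One call for the full paired dataset (spectra, sensory, latents)."""
    latents = generate_latents(config)
    return generate_spectra(latents, config), generate_sensory(latents, config), latents
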