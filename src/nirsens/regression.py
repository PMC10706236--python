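"""Support vector regression, PLS baseline, and k-fold RMSECV.

The epsilon-/nu-SVR duals are solved by scikit-learn's libsvm backend; the
solver is treated as a pluggable component whose contract (tube feasibility
on separable data, agreement with a reference quadratic-programming solution
on small problems) is validated by the test suite.  Fitted models are
detached from the solver: predictions are always computed in numpy from the
stored support vectors / dual coefficients (or PLS coefficients), so a
serialized-then-loaded model reproduces predictions bit-exactly.

RMSECV convention: pooled — the root of the mean of all held-out squared
errors across folds (not the mean of per-fold RMSEs); a ``pooled=False``
flag gives the fold-averaged alternative.  Fold assignment is contiguous
blocks after a seeded shuffle, so it is deterministic for a fixed seed.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from typing import Optional, Sequence, Union

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.svm import SVR, NuSVR

__all__ = [
    "SvrSpec",
    "PlsSpec",
    "FittedModel",
    "fit_svr",
    "fit_pls",
    "predict",
    "make_folds",
    "kfold_rmsecv",
]

SVR_TYPES = ("epsilon", "nu")
KERNELS = ("linear", "polynomial", "radial_base", "sigmoid")
_SKLEARN_KERNEL = {
    "linear": "linear",
    "polynomial": "poly",
    "radial_base": "rbf",
    "sigmoid": "sigmoid",
}
_SOLVER_TOL = 1e-6  # libsvm stopping tolerance; part of the solver contract


@dataclasses.dataclass
class SvrSpec:
    """SVR family, kernel and exactly the hyperparameters they license.

    epsilon-SVR takes (C, epsilon); nu-SVR takes (C, nu).  gamma applies to
    every kernel except linear; coef0 to polynomial and sigmoid; degree
    (integer, 2-5) to polynomial only.  Setting an unlicensed parameter is
    an error, as is omitting a required one.
    """

    svr_type: str
    kernel: str
    C: float
    epsilon: Optional[float] = None
    nu: Optional[float] = None
    gamma: Optional[float] = None
    coef0: Optional[float] = None
    degree: Optional[int] = None

    def __post_init__(self) -> None:
        if self.svr_type not in SVR_TYPES:
            raise ValueError(f"svr_type must be one of {SVR_TYPES}")
        if self.kernel not in KERNELS:
            raise ValueError(f"kernel must be one of {KERNELS}")
        if not self.C > 0:
            raise ValueError("C must be > 0")
        if self.svr_type == "epsilon":
            if self.epsilon is None or self.epsilon < 0:
                raise ValueError("epsilon-SVR requires epsilon >= 0")
            if self.nu is not None:
                raise ValueError("nu is not licensed for epsilon-SVR")
        else:
            if self.nu is None or not 0.0 < self.nu <= 1.0:
                raise ValueError("nu-SVR requires nu in (0, 1]")
            if self.epsilon is not None:
                raise ValueError("epsilon is not licensed for nu-SVR")
        if self.kernel == "linear":
            if self.gamma is not None:
                raise ValueError("gamma is not licensed for the linear kernel")
        else:
            if self.gamma is None or not self.gamma > 0:
                raise ValueError(f"kernel {self.kernel!r} requires gamma > 0")
        if self.kernel in ("polynomial", "sigmoid"):
            if self.coef0 is None:
                raise ValueError(f"kernel {self.kernel!r} requires coef0 (intercept)")
        elif self.coef0 is not None:
            raise ValueError("coef0 is only licensed for polynomial/sigmoid kernels")
        if self.kernel == "polynomial":
            if self.degree is None or not 2 <= int(self.degree) <= 5:
                raise ValueError("polynomial kernel requires integer degree in 2..5")
            self.degree = int(self.degree)
        elif self.degree is not None:
            raise ValueError("degree is only licensed for the polynomial kernel")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SvrSpec":
        return cls(**d)


@dataclasses.dataclass
class PlsSpec:
    """PLS1 baseline with a fixed number of latent variables."""

    n_components: int

    def __post_init__(self) -> None:
        if int(self.n_components) < 1:
            raise ValueError("n_components must be >= 1")
        self.n_components = int(self.n_components)

    def to_dict(self) -> dict:
        return {"n_components": self.n_components}


def _kernel_matrix(spec: SvrSpec, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """K(A, B) for the four kernels, matching the libsvm parameterization."""
    inner = A @ B.T
    if spec.kernel == "linear":
        return inner
    if spec.kernel == "radial_base":
        a2 = np.sum(A * A, axis=1)[:, None]
        b2 = np.sum(B * B, axis=1)[None, :]
        return np.exp(-spec.gamma * np.maximum(a2 + b2 - 2.0 * inner, 0.0))
    if spec.kernel == "polynomial":
        return (spec.gamma * inner + spec.coef0) ** spec.degree
    return np.tanh(spec.gamma * inner + spec.coef0)


@dataclasses.dataclass
class FittedModel:
    """A trained predictor detached from its solver.

    ``kind`` is "svr" or "pls".  For SVR the stored state is the support
    vectors, dual coefficients and intercept; for PLS the coefficient vector
    and X/Y means.  ``preprocessor`` optionally holds a fitted
    :class:`~nirsens.preprocess.PreprocessChain` so the model can consume raw
    spectra.  ``training_fingerprint`` hashes the training rows for audit.
    """

    kind: str
    spec: Union[SvrSpec, PlsSpec]
    n_features: int
    support_vectors: Optional[np.ndarray] = None
    dual_coef: Optional[np.ndarray] = None
    intercept: float = 0.0
    coef: Optional[np.ndarray] = None
    x_mean: Optional[np.ndarray] = None
    y_mean: float = 0.0
    preprocessor: Optional[object] = None
    training_fingerprint: str = ""

    # -- prediction ---------------------------------------------------------
    def predict(self, X) -> np.ndarray:
        from .containers import SpectraSet  # local import to avoid cycle

        if isinstance(X, SpectraSet):
            if self.preprocessor is None:
                raise ValueError("model has no preprocessor; pass a matrix")
            X = self.preprocessor.transform(X)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"channel mismatch: model expects {self.n_features} features, "
                f"got {X.shape[1]}"
            )
        if self.kind == "svr":
            K = _kernel_matrix(self.spec, X, self.support_vectors)
            return K @ self.dual_coef + self.intercept
        return (X - self.x_mean) @ self.coef + self.y_mean

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        def arr(a):
            return None if a is None else np.asarray(a).tolist()

        d = {
            "format_version": 1,
            "kind": self.kind,
            "spec": self.spec.to_dict(),
            "n_features": self.n_features,
            "support_vectors": arr(self.support_vectors),
            "dual_coef": arr(self.dual_coef),
            "intercept": self.intercept,
            "coef": arr(self.coef),
            "x_mean": arr(self.x_mean),
            "y_mean": self.y_mean,
            "training_fingerprint": self.training_fingerprint,
            "preprocessor": None,
        }
        if self.preprocessor is not None:
            d["preprocessor"] = self.preprocessor.to_dict()
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "FittedModel":
        from .preprocess import PreprocessChain

        def arr(a):
            return None if a is None else np.asarray(a, dtype=float)

        kind = d["kind"]
        spec = SvrSpec.from_dict(d["spec"]) if kind == "svr" else PlsSpec(**d["spec"])
        pre = d.get("preprocessor")
        return cls(
            kind=kind,
            spec=spec,
            n_features=int(d["n_features"]),
            support_vectors=arr(d.get("support_vectors")),
            dual_coef=arr(d.get("dual_coef")),
            intercept=float(d.get("intercept", 0.0)),
            coef=arr(d.get("coef")),
            x_mean=arr(d.get("x_mean")),
            y_mean=float(d.get("y_mean", 0.0)),
            preprocessor=None if pre is None else PreprocessChain.from_dict(pre),
            training_fingerprint=d.get("training_fingerprint", ""),
        )

    @classmethod
    def from_json(cls, text: str) -> "FittedModel":
        return cls.from_dict(json.loads(text))


def _fingerprint(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update(np.ascontiguousarray(y).tobytes())
    return h.hexdigest()[:16]


def _check_finite(X: np.ndarray, y: np.ndarray) -> None:
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in X or y")


def fit_svr(X: np.ndarray, y: np.ndarray, spec: SvrSpec) -> FittedModel:
    """Solve the epsilon-/nu-SVR dual for the given spec."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] < 2:
        raise ValueError("SVR needs at least 2 training rows")
    _check_finite(X, y)
    kw = dict(
        kernel=_SKLEARN_KERNEL[spec.kernel],
        C=spec.C,
        gamma=spec.gamma if spec.gamma is not None else "scale",
        coef0=spec.coef0 if spec.coef0 is not None else 0.0,
        degree=spec.degree if spec.degree is not None else 3,
        tol=_SOLVER_TOL,
        max_iter=-1,
        cache_size=64,
    )
    est = SVR(epsilon=spec.epsilon, **kw) if spec.svr_type == "epsilon" else NuSVR(nu=spec.nu, **kw)
    est.fit(X, y)
    return FittedModel(
        kind="svr",
        spec=spec,
        n_features=X.shape[1],
        support_vectors=est.support_vectors_.copy(),
        dual_coef=est.dual_coef_.ravel().copy(),
        intercept=float(est.intercept_[0]),
        training_fingerprint=_fingerprint(X, y),
    )


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    n_components: Optional[int] = None,
    cv_seed: int = 0,
    max_components: int = 15,
    k: int = 5,
) -> FittedModel:
    """PLS1 regression; component count picked by minimum RMSECV if not given."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    _check_finite(X, y)
    n, p = X.shape
    bound = min(n - 1, p)
    if n_components is None:
        grid = range(1, min(max_components, bound) + 1)
        folds = make_folds(n, min(k, n), cv_seed)
        scores = [
            kfold_rmsecv(X, y, PlsSpec(c), k=len(folds), seed=cv_seed, folds=folds)
            for c in grid
        ]
        n_components = int(np.argmin(scores)) + 1
    if not 1 <= n_components <= bound:
        raise ValueError(f"n_components must be in 1..{bound}, got {n_components}")
    est = PLSRegression(n_components=n_components, scale=False)
    est.fit(X, y)
    return FittedModel(
        kind="pls",
        spec=PlsSpec(n_components),
        n_features=p,
        coef=est.coef_.ravel().copy(),
        x_mean=X.mean(axis=0),
        y_mean=float(np.mean(y)),
        training_fingerprint=_fingerprint(X, y),
    )


def predict(model: FittedModel, X) -> np.ndarray:
    """Functional alias for :meth:`FittedModel.predict`."""
    return model.predict(X)


def _fit_any(X: np.ndarray, y: np.ndarray, spec: Union[SvrSpec, PlsSpec]) -> FittedModel:
    if isinstance(spec, SvrSpec):
        return fit_svr(X, y, spec)
    return fit_pls(X, y, n_components=spec.n_components)


def make_folds(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Contiguous blocks after a seeded shuffle; deterministic for a seed."""
    if not 2 <= k <= n:
        raise ValueError(f"k must satisfy 2 <= k <= {n}, got {k}")
    perm = np.random.default_rng(seed).permutation(n)
    return [np.sort(f) for f in np.array_split(perm, k)]


def kfold_rmsecv(
    X: np.ndarray,
    y: np.ndarray,
    spec: Union[SvrSpec, PlsSpec],
    k: int = 5,
    seed: int = 0,
    folds: Optional[Sequence[np.ndarray]] = None,
    pooled: bool = True,
) -> float:
    """k-fold cross-validated RMSE.

    Pooled convention (default): sqrt of the mean of all held-out squared
    errors.  ``pooled=False`` averages per-fold RMSEs instead.  Passing
    ``folds`` fixes the assignment explicitly (used by the tuner so every
    candidate sees identical folds).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if folds is None:
        folds = make_folds(n, k, seed)
    sq_errors = np.empty(n)
    fold_rmses = []
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        model = _fit_any(X[mask], y[mask], spec)
        resid = y[fold] - model.predict(X[fold])
        sq_errors[fold] = resid**2
        fold_rmses.append(float(np.sqrt(np.mean(resid**2))))
    if pooled:
        return float(np.sqrt(np.mean(sq_errors)))
    return float(np.mean(fold_rmses))
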