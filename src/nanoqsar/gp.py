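"""Gaussian-process regression with a normalized polynomial kernel.

The nano-QSAR predictor at the core of the package: descriptors are
standardized with training-set statistics, similarity is measured by the
cosine-normalized (inhomogeneous) polynomial kernel

    k(x, z) = p(x, z) / sqrt(p(x, x) p(z, z)),   p(x, z) = (x·z + c)^d,

with c = 1 when lower-order terms are included and c = 0 otherwise, and the
predictive mean/variance follow the standard GP equations with observation
noise sigma^2 solved through a Cholesky factorization of K + sigma^2 I.

Targets are centered on the training mean and scaled to unit variance
internally (the noise parameter stays in squared target units): the
normalized kernel has unit amplitude, so without this scaling the prior
would be incommensurate with targets in µg/mL and the noise level would act
on the wrong scale. With vanishing signal the model falls back to the mean
predictor rather than to zero.

Kernel degree, the lower-order constant, and the noise level are selected by
a deterministic grid search maximizing leave-one-out R^2 on the training
set (no values are assumed a priori).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger("nanoqsar")

#: Package-wide default seed recorded in every report.
DEFAULT_SEED = 20171017

SERIALIZATION_VERSION = 1

# Jitter policy: start at 1e-10 * trace(K)/n on the diagonal and escalate
# tenfold up to this ceiling before giving up.
_JITTER_START_REL = 1e-10
_JITTER_MAX = 1e-4


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScalerParams:
    """Training-set column means and standard deviations (ddof=1)."""

    means: np.ndarray
    sds: np.ndarray


def standardize_fit(X: np.ndarray) -> ScalerParams:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("standardization needs a 2-D matrix with >= 2 rows")
    if not np.all(np.isfinite(X)):
        raise ValueError("descriptor matrix contains non-finite values")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    if np.any(sds <= 0):
        bad = np.flatnonzero(sds <= 0)
        raise ValueError(f"zero-variance descriptor column(s): {bad.tolist()}")
    return ScalerParams(means=means, sds=sds)


def standardize_apply(params: ScalerParams, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return (X - params.means) / params.sds


def standardize_invert(params: ScalerParams, Z: np.ndarray) -> np.ndarray:
    return np.asarray(Z, dtype=float) * params.sds + params.means


# ---------------------------------------------------------------------------
# Kernel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KernelConfig:
    """Polynomial kernel configuration.

    degree
        Positive integer exponent d.
    include_lower_order
        Adds +1 inside the power ((x·z + 1)^d), bringing in all lower-order
        interaction terms.
    normalize
        Divide by the geometric mean of self-similarities, so k(x, x) = 1.
    """

    degree: int = 2
    include_lower_order: bool = True
    normalize: bool = True

    def __post_init__(self):
        if int(self.degree) != self.degree or self.degree < 1:
            raise ValueError("kernel degree must be a positive integer")

    @property
    def offset(self) -> float:
        return 1.0 if self.include_lower_order else 0.0


def _raw_poly(dots: np.ndarray, cfg: KernelConfig) -> np.ndarray:
    return (dots + cfg.offset) ** cfg.degree


def kernel_matrix(A: np.ndarray, B: np.ndarray, cfg: KernelConfig) -> np.ndarray:
    """Kernel matrix between the rows of A and of B (already standardized)."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("dimension mismatch between kernel arguments")
    P = _raw_poly(A @ B.T, cfg)
    if not cfg.normalize:
        return P
    da = _raw_poly(np.einsum("ij,ij->i", A, A), cfg)
    db = _raw_poly(np.einsum("ij,ij->i", B, B), cfg)
    if np.any(da <= 0) or np.any(db <= 0):
        raise ValueError(
            "zero self-similarity in normalized kernel (zero vector with c=0)"
        )
    return P / np.sqrt(np.outer(da, db))


def kernel_value(x: np.ndarray, z: np.ndarray, cfg: KernelConfig) -> float:
    """Kernel between two single (standardized) vectors."""
    x = np.asarray(x, dtype=float).ravel()
    z = np.asarray(z, dtype=float).ravel()
    if x.shape != z.shape:
        raise ValueError("dimension mismatch between kernel arguments")
    return float(kernel_matrix(x[None, :], z[None, :], cfg)[0, 0])


# ---------------------------------------------------------------------------
# GP fit / predict
# ---------------------------------------------------------------------------

@dataclass
class GPModel:
    """Fitted Gaussian-process state.

    ``train_inputs`` are standardized descriptors; ``train_targets`` are in
    EC50 units (µg/mL). ``weights`` solves (K + sigma^2/sd^2 I) a = y_std
    with y_std = (y - y_mean)/target_sd, so the predictive mean is
    target_sd * k^T a + y_mean.
    """

    scaler: ScalerParams
    kernel: KernelConfig
    noise_variance: float
    train_inputs: np.ndarray
    train_targets: np.ndarray
    target_mean: float
    target_sd: float
    weights: np.ndarray
    cholesky_lower: np.ndarray
    jitter: float = 0.0

    @property
    def n_train(self) -> int:
        return self.train_inputs.shape[0]


def gp_fit(
    X: np.ndarray,
    y: np.ndarray,
    cfg: KernelConfig,
    noise_variance: float,
    scaler: ScalerParams | None = None,
    standardized: bool = False,
) -> GPModel:
    """Fit the GP.

    By default ``X`` is raw descriptors: a scaler is fitted on them (or the
    provided one applied) and stored in the model. Pass ``standardized=True``
    with an explicit ``scaler`` when X is already transformed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0] or X.shape[0] < 2:
        raise ValueError("need matching X rows and y entries (>= 2)")
    if noise_variance < 0:
        raise ValueError("noise variance must be nonnegative")
    if standardized:
        if scaler is None:
            raise ValueError("standardized=True requires an explicit scaler")
        Z = X
    else:
        scaler = scaler or standardize_fit(X)
        Z = standardize_apply(scaler, X)

    K = kernel_matrix(Z, Z, cfg)
    n = K.shape[0]
    ym = float(y.mean())
    sd = float(y.std())
    if sd == 0.0:
        sd = 1.0  # constant targets: centering already removes everything
    base = K + (noise_variance / sd**2) * np.eye(n)
    jitter = _JITTER_START_REL * np.trace(K) / n
    used = 0.0
    L = None
    while True:
        try:
            L = np.linalg.cholesky(base + used * np.eye(n))
            break
        except np.linalg.LinAlgError:
            used = jitter if used == 0.0 else used * 10.0
            if used > _JITTER_MAX:
                raise np.linalg.LinAlgError(
                    f"kernel matrix not positive definite up to jitter {_JITTER_MAX}"
                )
    alpha = np.linalg.solve(L.T, np.linalg.solve(L, (y - ym) / sd))
    return GPModel(
        scaler=scaler, kernel=cfg, noise_variance=float(noise_variance),
        train_inputs=Z, train_targets=y, target_mean=ym, target_sd=sd,
        weights=alpha, cholesky_lower=L, jitter=used,
    )


def gp_predict(
    model: GPModel,
    X_new: np.ndarray,
    standardized: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Predictive mean and variance at new points.

    Raw descriptors are transformed with the model's (training-set) scaler.
    Negative variances beyond a -1e-8 numerical margin trigger a warning;
    all are clipped at zero.
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    Z = X_new if standardized else standardize_apply(model.scaler, X_new)
    if Z.shape[1] != model.train_inputs.shape[1]:
        raise ValueError("query dimensionality does not match the model")
    Ks = kernel_matrix(Z, model.train_inputs, model.kernel)
    mean = model.target_sd * (Ks @ model.weights) + model.target_mean
    V = np.linalg.solve(model.cholesky_lower, Ks.T)
    kss = np.array([kernel_value(z, z, model.kernel) for z in Z])
    var = model.target_sd**2 * (kss - np.einsum("ij,ij->j", V, V))
    if np.any(var < -1e-8 * max(model.target_sd**2, 1.0)):
        warnings.warn("negative predictive variance beyond numerical margin; clipped")
    return mean, np.clip(var, 0.0, None)


# ---------------------------------------------------------------------------
# Hyperparameter selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HyperGrid:
    """Grid for the leave-one-out search.

    ``noise_ratios`` multiply the training-target variance (ddof=0), keeping
    the sigma^2 grid meaningful regardless of the target scale.
    """

    degrees: tuple[int, ...] = (1, 2, 3)
    offsets: tuple[int, ...] = (0, 1)
    noise_ratios: tuple[float, ...] = tuple(
        float(r) for r in np.logspace(-6, 1, 15)
    )

    def __post_init__(self):
        if not (self.degrees and self.offsets and self.noise_ratios):
            raise ValueError("empty hyperparameter grid")


def _loo_r2(Z: np.ndarray, y: np.ndarray, cfg: KernelConfig, s2: float,
            scaler: ScalerParams) -> float:
    n = len(y)
    preds = np.empty(n)
    for i in range(n):
        idx = np.arange(n) != i
        m = gp_fit(Z[idx], y[idx], cfg, s2, scaler=scaler, standardized=True)
        mean, _ = gp_predict(m, Z[i: i + 1], standardized=True)
        preds[i] = mean[0]
    sst = np.sum((y - y.mean()) ** 2)
    return float(1.0 - np.sum((y - preds) ** 2) / sst)


def select_hyperparameters(
    X_train: np.ndarray,
    y_train: np.ndarray,
    grid: HyperGrid | None = None,
) -> tuple[KernelConfig, float, dict]:
    """Deterministic grid search maximizing leave-one-out R^2 on the
    training set.

    Ties break toward (lower degree, larger sigma^2, no lower-order term).
    Returns (kernel config, noise variance, diagnostics with the whole
    scored grid).
    """
    grid = grid or HyperGrid()
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float).ravel()
    scaler = standardize_fit(X_train)
    Z = standardize_apply(scaler, X_train)
    var_y = float(np.var(y_train))
    scored = []
    for d in grid.degrees:
        for c in grid.offsets:
            cfg = KernelConfig(degree=d, include_lower_order=bool(c), normalize=True)
            for ratio in grid.noise_ratios:
                s2 = ratio * var_y
                r2 = _loo_r2(Z, y_train, cfg, s2, scaler)
                scored.append({"degree": d, "offset": c, "noise_variance": s2,
                               "noise_ratio": ratio, "loo_r2": r2})
    # maximize LOO R^2; ties -> lower degree, then larger sigma^2, then c=0
    best = max(
        scored,
        key=lambda e: (e["loo_r2"], -e["degree"], e["noise_variance"], -e["offset"]),
    )
    cfg = KernelConfig(degree=best["degree"],
                       include_lower_order=bool(best["offset"]), normalize=True)
    logger.info(
        "selected kernel degree=%d c=%d sigma^2=%.4g (LOO R^2=%.4f)",
        cfg.degree, best["offset"], best["noise_variance"], best["loo_r2"],
    )
    return cfg, float(best["noise_variance"]), {"grid": scored, "best": best}


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def model_to_json(model: GPModel) -> str:
    doc = {
        "format_version": SERIALIZATION_VERSION,
        "scaler": {"means": model.scaler.means.tolist(),
                   "sds": model.scaler.sds.tolist()},
        "kernel": {"degree": model.kernel.degree,
                   "include_lower_order": model.kernel.include_lower_order,
                   "normalize": model.kernel.normalize},
        "noise_variance": model.noise_variance,
        "train_inputs": model.train_inputs.tolist(),
        "train_targets": model.train_targets.tolist(),
        "target_mean": model.target_mean,
        "target_sd": model.target_sd,
        "weights": model.weights.tolist(),
        "cholesky_lower": model.cholesky_lower.tolist(),
        "jitter": model.jitter,
    }
    return json.dumps(doc)


def model_from_json(text: str) -> GPModel:
    doc = json.loads(text)
    if doc.get("format_version") != SERIALIZATION_VERSION:
        raise ValueError(f"unsupported model format version: {doc.get('format_version')}")
    return GPModel(
        scaler=ScalerParams(means=np.array(doc["scaler"]["means"]),
                            sds=np.array(doc["scaler"]["sds"])),
        kernel=KernelConfig(**doc["kernel"]),
        noise_variance=doc["noise_variance"],
        train_inputs=np.array(doc["train_inputs"]),
        train_targets=np.array(doc["train_targets"]),
        target_mean=doc["target_mean"],
        target_sd=doc["target_sd"],
        weights=np.array(doc["weights"]),
        cholesky_lower=np.array(doc["cholesky_lower"]),
        jitter=doc["jitter"],
    )


def save_model(model: GPModel, path: str | Path) -> None:
    Path(path).write_text(model_to_json(model), encoding="utf-8")


def load_model(path: str | Path) -> GPModel:
    return model_from_json(Path(path).read_text(encoding="utf-8"))
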