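"""Model-quality machinery: calibration/validation statistics, bootstrap
(bagging) validation, and the Y-scrambling chance-correlation test.

Statistics follow the standard QSAR definitions:

    R^2      = 1 - sum_i (y_i - yhat_i)^2 / sum_i (y_i - ybar_train)^2
    RMSEC    = sqrt(mean training squared residual)
    Q^2_EXT  = 1 - sum_j (y_j - yhat_j)^2 / sum_j (y_j - ybar_val)^2
    RMSEP    = sqrt(mean test squared residual)

Q^2_EXT centers its denominator on the *validation-set* mean by default; a
flag switches to training-mean centering (both conventions circulate in the
QSAR literature and differ only in the denominator).

Bagging validation refits the model on bootstrap resamples of the training
rows and averages each resample model's R^2 over its out-of-bag rows;
Y-scrambling permutes the response across the training rows with descriptors
fixed and refits the full pipeline under frozen hyperparameters, so the
resulting distribution measures chance correlation rather than re-tuning.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .dataset import ModelingTable
from .gp import (
    DEFAULT_SEED, GPModel, KernelConfig, gp_fit, gp_predict, standardize_fit,
)

logger = logging.getLogger("nanoqsar")

REPORT_SCHEMA_VERSION = 1


def r_squared(obs: np.ndarray, pred: np.ndarray,
              mean_reference: np.ndarray) -> float:
    """1 - SSE/SST with SST centered on the mean of ``mean_reference``
    (training set for R^2, validation set for Q^2_EXT)."""
    obs = np.asarray(obs, dtype=float).ravel()
    pred = np.asarray(pred, dtype=float).ravel()
    ref = np.asarray(mean_reference, dtype=float).ravel()
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("obs and pred must match with length >= 2")
    sst = float(np.sum((obs - ref.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("zero denominator: observed values are constant")
    return float(1.0 - np.sum((obs - pred) ** 2) / sst)


def rmse(obs: np.ndarray, pred: np.ndarray) -> float:
    obs = np.asarray(obs, dtype=float).ravel()
    pred = np.asarray(pred, dtype=float).ravel()
    if obs.size == 0 or obs.shape != pred.shape:
        raise ValueError("obs and pred must match and be nonempty")
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


@dataclass
class ValidationReport:
    r2_train: float
    rmsec: float
    q2_ext: float
    rmsep: float
    r2_bagging: float
    rmse_bagging: float
    n_train: int
    n_test: int
    residuals: np.ndarray          # observed - predicted, training then test
    labels: list[str]
    observed: np.ndarray
    predicted: np.ndarray
    statuses: list[str]
    ec50_variant: str
    q2_centering: str = "validation_mean"
    seed: int = DEFAULT_SEED
    schema_version: int = REPORT_SCHEMA_VERSION

    def to_json(self) -> str:
        doc = asdict(self)
        for key in ("residuals", "observed", "predicted"):
            doc[key] = np.asarray(doc[key]).tolist()
        return json.dumps(doc, indent=2)

    def to_text_table(self) -> str:
        """Plain-text table mirroring the modeling-table layout
        (label, status, observed, predicted, error)."""
        lines = [f"{'sample':<16}{'status':<20}{'observed':>10}{'predicted':>11}{'error':>9}"]
        for lab, st, o, p in zip(self.labels, self.statuses,
                                 self.observed, self.predicted):
            lines.append(f"{lab:<16}{st:<20}{o:>10.2f}{p:>11.2f}{abs(o - p):>9.2f}")
        lines.append("")
        lines.append(
            f"R2(train)={self.r2_train:.4f}  RMSEC={self.rmsec:.2f}  "
            f"Q2_EXT={self.q2_ext:.4f}  RMSEP={self.rmsep:.2f}  "
            f"R2_bagging={self.r2_bagging:.4f}  RMSE_bagging={self.rmse_bagging:.2f}"
        )
        lines.append(f"variant={self.ec50_variant}  n={self.n_train}  k={self.n_test}")
        return "\n".join(lines)


@dataclass
class ScramblingResult:
    n_permutations: int
    r2_values: np.ndarray
    r2_bagging_values: np.ndarray
    rmse_values: np.ndarray
    seed: int
    n_failed: int = 0

    def to_json(self) -> str:
        return json.dumps({
            "schema_version": REPORT_SCHEMA_VERSION,
            "n_permutations": self.n_permutations,
            "r2_values": self.r2_values.tolist(),
            "r2_bagging_values": self.r2_bagging_values.tolist(),
            "rmse_values": self.rmse_values.tolist(),
            "seed": self.seed,
            "n_failed": self.n_failed,
        }, indent=2)


def _fit_training_gp(table: ModelingTable, cfg: KernelConfig,
                     noise_variance: float) -> GPModel:
    train = table.subset(table.training_mask)
    return gp_fit(train.descriptor_matrix(), train.ec50, cfg, noise_variance)


def bagging_validate(
    table: ModelingTable,
    cfg: KernelConfig,
    noise_variance: float,
    B: int = 100,
    seed: int = DEFAULT_SEED,
) -> tuple[float, float, dict[str, float]]:
    """Bootstrap-aggregated validation on the training rows.

    Draws ``B`` resamples (size n, with replacement) of the training rows,
    refits the GP on each, scores each model's R^2 on its out-of-bag rows
    (centered on the out-of-bag observed mean), and averages. Resamples with
    no out-of-bag rows are redrawn; resamples whose out-of-bag set is too
    small or degenerate for R^2 (fewer than 2 rows, or constant observed)
    contribute to the out-of-bag predictions but not to the R^2 average.

    Returns (r2_bagging, rmse_bagging, per-sample mean out-of-bag
    predictions); rmse_bagging is the RMSE of those averaged out-of-bag
    predictions against the observed training values.
    """
    if B < 2:
        raise ValueError("need at least 2 bootstrap resamples")
    train = table.subset(table.training_mask)
    n = train.n
    if n < 4:
        raise ValueError("need at least 4 training rows for bagging")
    X = train.descriptor_matrix()
    y = train.ec50
    rng = np.random.default_rng(seed)
    r2s: list[float] = []
    oob_sum = np.zeros(n)
    oob_count = np.zeros(n, dtype=int)
    for _ in range(B):
        while True:
            idx = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), idx)
            if oob.size > 0:
                break
            logger.info("bootstrap resample had no out-of-bag rows; redrawn")
        try:
            model = gp_fit(X[idx], y[idx], cfg, noise_variance)
        except (np.linalg.LinAlgError, ValueError) as exc:
            logger.info("bootstrap refit failed (%s); resample skipped", exc)
            continue
        pred, _ = gp_predict(model, X[oob])
        oob_sum[oob] += pred
        oob_count[oob] += 1
        if oob.size >= 2 and np.ptp(y[oob]) > 0:
            r2s.append(r_squared(y[oob], pred, y[oob]))
    if not r2s:
        raise RuntimeError("no bootstrap resample produced a scorable model")
    covered = oob_count > 0
    oob_mean = np.full(n, np.nan)
    oob_mean[covered] = oob_sum[covered] / oob_count[covered]
    rmse_bag = rmse(y[covered], oob_mean[covered])
    per_sample = {lab: float(p) for lab, p in zip(train.labels, oob_mean)}
    return float(np.mean(r2s)), rmse_bag, per_sample


def external_validation(
    model: GPModel,
    table: ModelingTable,
    B: int = 100,
    seed: int = DEFAULT_SEED,
    q2_centering: str = "validation_mean",
) -> ValidationReport:
    """Fill the full validation report for a model trained on the table's
    training rows only.

    A model whose training size or targets do not match the table's training
    rows is rejected (leakage guard): test rows must never have entered
    fitting or scaling.
    """
    train = table.subset(table.training_mask)
    test = table.subset(table.test_mask)
    if test.n == 0:
        raise ValueError("empty test set")
    if model.n_train != train.n or not np.allclose(
            np.sort(model.train_targets), np.sort(train.ec50)):
        raise ValueError(
            "model was not trained on exactly the table's training rows "
            "(possible test-set leakage)"
        )
    pred_train, _ = gp_predict(model, train.descriptor_matrix())
    pred_test, _ = gp_predict(model, test.descriptor_matrix())
    if q2_centering == "validation_mean":
        q2 = r_squared(test.ec50, pred_test, test.ec50)
    elif q2_centering == "training_mean":
        q2 = r_squared(test.ec50, pred_test, train.ec50)
    else:
        raise ValueError(f"unknown Q2 centering: {q2_centering!r}")
    r2_bag, rmse_bag, _ = bagging_validate(
        table, model.kernel, model.noise_variance, B=B, seed=seed)
    return ValidationReport(
        r2_train=r_squared(train.ec50, pred_train, train.ec50),
        rmsec=rmse(train.ec50, pred_train),
        q2_ext=q2,
        rmsep=rmse(test.ec50, pred_test),
        r2_bagging=r2_bag,
        rmse_bagging=rmse_bag,
        n_train=train.n,
        n_test=test.n,
        residuals=np.concatenate([train.ec50 - pred_train, test.ec50 - pred_test]),
        labels=train.labels + test.labels,
        observed=np.concatenate([train.ec50, test.ec50]),
        predicted=np.concatenate([pred_train, pred_test]),
        statuses=[s.value for s in train.split_status + test.split_status],
        ec50_variant=table.ec50_variant,
        q2_centering=q2_centering,
        seed=seed,
    )


def y_scramble(
    table: ModelingTable,
    cfg: KernelConfig,
    noise_variance: float,
    n_permutations: int = 50,
    seed: int = DEFAULT_SEED,
    bagging_B: int = 100,
) -> ScramblingResult:
    """Y-scrambling (dependent-variable scrambling) test.

    For each permutation the EC50 values of the training rows are shuffled
    (identity permutations are redrawn), the pipeline is refit with the
    reference model's hyperparameters frozen, and training R^2, bagging R^2
    and training RMSE are recorded.
    """
    if n_permutations < 10:
        raise ValueError("need at least 10 permutations")
    train = table.subset(table.training_mask)
    n = train.n
    rng = np.random.default_rng(seed)
    r2s = np.empty(n_permutations)
    r2bags = np.empty(n_permutations)
    rmses = np.empty(n_permutations)
    n_failed = 0
    for b in range(n_permutations):
        while True:
            perm = rng.permutation(n)
            if not np.array_equal(perm, np.arange(n)):
                break
        y_perm = train.ec50[perm]
        scrambled = table.with_ec50(
            _scatter_training(table, y_perm))
        try:
            model = _fit_training_gp(scrambled, cfg, noise_variance)
            pred, _ = gp_predict(
                model, scrambled.subset(scrambled.training_mask).descriptor_matrix())
            r2s[b] = r_squared(y_perm, pred, y_perm)
            rmses[b] = rmse(y_perm, pred)
            bag_seed = int(rng.integers(0, 2**31 - 1))
            r2bags[b], _, _ = bagging_validate(
                scrambled, cfg, noise_variance, B=bagging_B, seed=bag_seed)
        except (np.linalg.LinAlgError, ValueError, RuntimeError) as exc:
            logger.info("scrambling permutation %d failed: %s", b, exc)
            r2s[b] = r2bags[b] = rmses[b] = np.nan
            n_failed += 1
    return ScramblingResult(
        n_permutations=n_permutations, r2_values=r2s,
        r2_bagging_values=r2bags, rmse_values=rmses,
        seed=seed, n_failed=n_failed,
    )


def _scatter_training(table: ModelingTable, y_train_new: np.ndarray) -> np.ndarray:
    """Full-length EC50 vector with training entries replaced in order."""
    out = table.ec50.copy()
    out[table.training_mask] = y_train_new
    return out


def scrambling_p_value(result: ScramblingResult, reference_r2: float) -> float:
    """Empirical one-sided p-value of the reference R^2 against the
    scrambled distribution ((#{scrambled >= reference} + 1)/(m + 1))."""
    vals = result.r2_values[np.isfinite(result.r2_values)]
    return float((np.sum(vals >= reference_r2) + 1) / (vals.size + 1))
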