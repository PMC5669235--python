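"""EC50 estimation from viability-concentration data and MIC determination
from turbidity dilution series.

Cytotoxicity: viability (% of untreated control, WST-8-type readout) versus
nanoparticle concentration is fitted with a four-parameter log-logistic
(Hill) curve

    v(c) = bottom + (top - bottom) / (1 + (c / ec50)^hill),

by bounded nonlinear least squares; EC50 is the concentration at the
midpoint between the fitted asymptotes. A fit whose EC50 falls outside the
tested concentration range — or data showing no transition at all — yields a
censored result (e.g. ">300"), never an extrapolated number.

Antibacterial activity: MIC is the lowest concentration of a descending
twofold dilution series whose mean turbidity decrease relative to the
compound-free growth control is at least the threshold (80% by the assay's
definition; "at least" makes the boundary inclusive).
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares

from .dataset import Censored

logger = logging.getLogger("nanoqsar")

#: Concentration series of the cytotoxicity assay: twofold steps from
#: 1.56 µg/mL with the top dose capped at 300 µg/mL (nine points).
CHO_CONCENTRATIONS = np.array(
    [1.56, 3.12, 6.25, 12.5, 25.0, 50.0, 100.0, 200.0, 300.0]
)

# Optimizer budget / bounds (viability in %, hill dimensionless).
_MAX_NFEV = 1000
_COST_TOL = 1e-8
_BOUND_BOTTOM = (0.0, 100.0)
_BOUND_TOP_MAX = 120.0
_BOUND_HILL = (0.1, 10.0)

#: Data with all viabilities at or above this level show no effect.
_NO_EFFECT_LEVEL = 95.0


@dataclass(frozen=True)
class DoseResponseFit:
    """Result of a 4-parameter log-logistic fit.

    ``ec50`` is None when the result is censored; ``censored`` then carries
    the marker (a :class:`~nanoqsar.dataset.Censored` bound).
    """

    bottom: float
    top: float
    ec50: float | None
    hill: float
    residual_sse: float
    converged: bool
    n_points: int
    censored: Censored | None = None

    @property
    def is_censored(self) -> bool:
        return self.censored is not None


@dataclass(frozen=True)
class MicResult:
    mic: float | Censored
    tested_concentrations: np.ndarray   # descending twofold series, µg/mL
    decrease_fraction: np.ndarray       # mean per concentration, <= 1

    @property
    def is_censored(self) -> bool:
        return isinstance(self.mic, Censored)


def viability_percent(od_treated: float, od_control: float) -> float:
    """Viability as 100 x treated/control absorbance. Values above 100 are
    permitted (and logged): slight stimulation relative to control."""
    if od_control <= 0:
        raise ValueError("control absorbance must be positive")
    v = 100.0 * od_treated / od_control
    if v > 100.0:
        logger.info("viability above 100%% (%.1f): treated exceeds control", v)
    return v


def four_pl(conc, bottom, top, ec50, hill):
    """The 4-parameter log-logistic viability curve (decreasing in conc)."""
    conc = np.asarray(conc, dtype=float)
    return bottom + (top - bottom) / (1.0 + (conc / ec50) ** hill)


def fit_concentration_response(
    concentrations: np.ndarray,
    viability: np.ndarray,
    replicate_viability: np.ndarray | None = None,
) -> DoseResponseFit:
    """Fit the 4PL curve by bounded least squares.

    ``concentrations``/``viability`` are per-concentration values; if
    replicate columns are supplied via ``replicate_viability`` (shape
    n_conc x n_rep) they are averaged with equal weight first.
    """
    conc = np.asarray(concentrations, dtype=float).ravel()
    if replicate_viability is not None:
        viab = np.asarray(replicate_viability, dtype=float).mean(axis=1)
    else:
        viab = np.asarray(viability, dtype=float).ravel()
    if conc.shape != viab.shape:
        raise ValueError("concentration and viability vectors differ in length")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    order = np.argsort(conc)
    conc, viab = conc[order], viab[order]
    if len(np.unique(conc)) < 5:
        raise ValueError("need at least 5 distinct concentrations")
    cmin, cmax = conc[0], conc[-1]

    if np.all(viab >= _NO_EFFECT_LEVEL):
        # no effect observed anywhere in the tested range
        return DoseResponseFit(
            bottom=float(viab.min()), top=float(viab.max()), ec50=None,
            hill=math.nan, residual_sse=math.nan, converged=True,
            n_points=len(conc), censored=Censored(cmax),
        )

    top0 = float(viab.max())
    bot0 = float(max(viab.min(), 0.0))
    mid = (top0 + bot0) / 2.0
    ec0 = float(conc[np.argmin(np.abs(viab - mid))])

    def residuals(theta):
        b, t, e, h = theta
        return four_pl(conc, b, t, e, h) - viab

    lo = [_BOUND_BOTTOM[0], bot0, cmin / 100.0, _BOUND_HILL[0]]
    hi = [min(_BOUND_BOTTOM[1], top0), _BOUND_TOP_MAX, cmax * 100.0, _BOUND_HILL[1]]
    x0 = np.clip([bot0, top0, ec0, 1.0], lo, hi)
    sol = least_squares(residuals, x0, bounds=(lo, hi), ftol=_COST_TOL,
                        xtol=1e-12, gtol=None, max_nfev=_MAX_NFEV)
    b, t, e, h = sol.x
    sse = float(2.0 * sol.cost)
    if not sol.success:
        return DoseResponseFit(bottom=float(b), top=float(t), ec50=None,
                               hill=float(h), residual_sse=sse, converged=False,
                               n_points=len(conc), censored=None)
    if e > cmax:
        # midpoint never reached within the tested range
        return DoseResponseFit(bottom=float(b), top=float(t), ec50=None,
                               hill=float(h), residual_sse=sse, converged=True,
                               n_points=len(conc), censored=Censored(cmax))
    if e < cmin:
        return DoseResponseFit(bottom=float(b), top=float(t), ec50=None,
                               hill=float(h), residual_sse=sse, converged=True,
                               n_points=len(conc), censored=Censored(cmin))
    return DoseResponseFit(bottom=float(b), top=float(t), ec50=float(e),
                           hill=float(h), residual_sse=sse, converged=True,
                           n_points=len(conc), censored=None)


def mic_from_turbidity(
    od_wells: np.ndarray,
    concentrations: np.ndarray,
    od_growth_control: float,
    threshold: float = 0.80,
) -> MicResult:
    """MIC from a concentration x replicate turbidity matrix.

    ``concentrations`` must be a strictly descending twofold series. The MIC
    is the lowest concentration whose mean turbidity decrease relative to the
    growth control is >= ``threshold``; if none qualifies the result is
    censored at the maximum tested concentration.
    """
    od = np.atleast_2d(np.asarray(od_wells, dtype=float))
    conc = np.asarray(concentrations, dtype=float).ravel()
    if od.size == 0 or conc.size == 0:
        raise ValueError("empty plate")
    if od.shape[0] != conc.size:
        raise ValueError("one row of wells per concentration required")
    if od_growth_control <= 0:
        raise ValueError("growth control absorbance must be positive")
    if np.any(np.diff(conc) >= 0):
        raise ValueError("concentrations must be strictly descending")
    ratios = conc[:-1] / conc[1:]
    if not np.allclose(ratios, 2.0, rtol=0.05):
        raise ValueError("concentrations must form a twofold dilution series")
    decrease = 1.0 - od.mean(axis=1) / od_growth_control
    qualifying = np.flatnonzero(decrease >= threshold)
    if qualifying.size == 0:
        mic: float | Censored = Censored(conc[0])
    else:
        mic = float(conc[qualifying].min())
    return MicResult(mic=mic, tested_concentrations=conc,
                     decrease_fraction=decrease)


# ---------------------------------------------------------------------------
# Plate CSV I/O (long format: concentration,replicate,od; concentration 0
# rows are untreated controls)
# ---------------------------------------------------------------------------

def read_plate_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray, float]:
    """Read a plate CSV; returns (concentrations, viability matrix averaged
    input, control OD). Viability is computed against the mean control OD."""
    path = Path(path)
    rows: list[tuple[float, float]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for field_name in ("concentration", "replicate", "od"):
            if field_name not in (reader.fieldnames or []):
                raise ValueError(f"{path}: plate CSV missing column {field_name!r}")
        for lineno, row in enumerate(reader, start=2):
            try:
                rows.append((float(row["concentration"]), float(row["od"])))
            except ValueError as exc:
                raise ValueError(f"{path}, line {lineno}: {exc}") from exc
    data = np.array(rows)
    controls = data[data[:, 0] == 0.0, 1]
    if controls.size == 0:
        raise ValueError(f"{path}: no control wells (concentration 0)")
    control_od = float(controls.mean())
    treated = data[data[:, 0] > 0.0]
    conc = np.unique(treated[:, 0])
    viab = np.array([
        np.mean([viability_percent(od, control_od)
                 for od in treated[treated[:, 0] == c, 1]])
        for c in conc
    ])
    return conc, viab, control_od
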