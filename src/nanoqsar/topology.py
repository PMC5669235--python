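"""Per-topology polynomial sub-models.

The GP model is a black box; these ordinary least-squares polynomials in the
raw (unstandardized) descriptors are the interpretable companions, one per
structural class, using the pairing

    pure (monometallic) -> average particle size (nm)
    alloy               -> BET surface area (m2/g)
    core-shell          -> average particle size (nm)

R^2 is computed against the subset's own mean; RMSE over the subset. The
unmodified TiO2 control (censored EC50, size 0) never enters these fits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dataset import ModelingTable, Topology

logger = logging.getLogger("nanoqsar")

#: descriptor paired with each topology in the sub-models
TOPOLOGY_DESCRIPTOR = {
    Topology.PURE: "average_size",
    Topology.ALLOY: "bet_surface",
    Topology.CORE_SHELL: "average_size",
}

#: polynomial order of the selected (reported) sub-model per topology
SELECTED_ORDER = {
    Topology.PURE: 3,
    Topology.ALLOY: 2,
    Topology.CORE_SHELL: 2,
}

#: allowed extrapolation beyond the fitted descriptor range, as a fraction
#: of the range span
_EXTRAPOLATION_MARGIN = 0.10


@dataclass(frozen=True)
class TopologyPolyFit:
    topology: Topology
    descriptor: str                 # "average_size" or "bet_surface"
    order: int
    coefficients: np.ndarray        # highest order first (numpy convention)
    r2: float
    rmse: float
    n_points: int
    x_min: float
    x_max: float

    def to_dict(self) -> dict:
        return {
            "topology": self.topology.value,
            "descriptor": self.descriptor,
            "order": self.order,
            "coefficients": self.coefficients.tolist(),
            "r2": self.r2,
            "rmse": self.rmse,
            "n_points": self.n_points,
            "x_range": [self.x_min, self.x_max],
        }


def _descriptor_values(table: ModelingTable, descriptor: str) -> np.ndarray:
    if descriptor == "average_size":
        return table.average_size
    if descriptor == "bet_surface":
        return table.bet_surface
    raise ValueError(f"unknown descriptor: {descriptor!r}")


def fit_topology_polynomial(
    table: ModelingTable,
    topology: Topology,
    descriptor: str,
    order: int,
) -> TopologyPolyFit:
    """OLS polynomial of the given order for one topology subset."""
    if order not in (1, 2, 3):
        raise ValueError("polynomial order must be 1, 2 or 3")
    mask = np.array([t == topology for t in table.topology])
    if not mask.any():
        raise ValueError(f"no samples with topology {topology.value}")
    x = _descriptor_values(table, descriptor)[mask]
    y = table.ec50[mask]
    if len(x) <= order:
        raise ValueError(
            f"{topology.value}: {len(x)} points cannot support order {order}"
        )
    if len(np.unique(x)) <= order:
        raise ValueError(
            f"{topology.value}: only {len(np.unique(x))} distinct descriptor "
            f"values; order {order} is degenerate"
        )
    coeffs = np.polyfit(x, y, order)
    pred = np.polyval(coeffs, x)
    sst = np.sum((y - y.mean()) ** 2)
    r2 = float(1.0 - np.sum((y - pred) ** 2) / sst)
    return TopologyPolyFit(
        topology=topology, descriptor=descriptor, order=order,
        coefficients=coeffs, r2=r2,
        rmse=float(np.sqrt(np.mean((y - pred) ** 2))),
        n_points=int(mask.sum()), x_min=float(x.min()), x_max=float(x.max()),
    )


def table4(table: ModelingTable) -> dict[Topology, dict[int, float]]:
    """R^2 grid (topology x polynomial order 1..3) under the canonical
    descriptor pairing; full precision (round only for display)."""
    grid: dict[Topology, dict[int, float]] = {}
    for topo, desc in TOPOLOGY_DESCRIPTOR.items():
        grid[topo] = {
            order: fit_topology_polynomial(table, topo, desc, order).r2
            for order in (1, 2, 3)
        }
    return grid


def render_table4(grid: dict[Topology, dict[int, float]]) -> str:
    lines = [f"{'type of NPs':<14}{'linear':>8}{'2nd order':>11}{'3rd order':>11}"]
    for topo, row in grid.items():
        lines.append(
            f"{topo.value:<14}{row[1]:>8.2f}{row[2]:>11.2f}{row[3]:>11.2f}"
        )
    return "\n".join(lines)


def selected_fits(table: ModelingTable) -> dict[Topology, TopologyPolyFit]:
    """The reported sub-model per topology (pure: cubic vs average size;
    alloy: quadratic vs BET; core-shell: quadratic vs average size)."""
    return {
        topo: fit_topology_polynomial(
            table, topo, TOPOLOGY_DESCRIPTOR[topo], SELECTED_ORDER[topo])
        for topo in TOPOLOGY_DESCRIPTOR
    }


def per_type_rmse(fits: dict[Topology, TopologyPolyFit]) -> dict[Topology, float]:
    """RMSE of each selected sub-model over its own subset."""
    missing = [t for t in TOPOLOGY_DESCRIPTOR if t not in fits]
    if missing:
        raise ValueError(f"missing topology fit(s): {[t.value for t in missing]}")
    return {topo: fit.rmse for topo, fit in fits.items()}


@dataclass(frozen=True)
class EquationPrediction:
    ec50: float                 # µg/mL
    rmse: float                 # the fit's RMSE, carried as uncertainty
    extrapolated: bool


def predict_from_equation(
    fit: TopologyPolyFit,
    descriptor_value: float,
    topology: Topology | None = None,
) -> EquationPrediction:
    """Evaluate a topology sub-model.

    Each equation is applicable only to its own topology: a declared
    ``topology`` that disagrees with the fit's is an error. Queries beyond
    the fitted descriptor range plus a 10%-of-span margin are flagged as
    extrapolated (and logged).
    """
    if topology is not None and topology != fit.topology:
        raise ValueError(
            f"equation for {fit.topology.value} cannot predict a "
            f"{topology.value} sample"
        )
    span = fit.x_max - fit.x_min
    margin = _EXTRAPOLATION_MARGIN * span
    extrapolated = not (fit.x_min - margin <= descriptor_value <= fit.x_max + margin)
    if extrapolated:
        logger.warning(
            "descriptor value %.3g outside fitted range [%.3g, %.3g] (+/-10%%)",
            descriptor_value, fit.x_min, fit.x_max,
        )
    return EquationPrediction(
        ec50=float(np.polyval(fit.coefficients, descriptor_value)),
        rmse=fit.rmse, extrapolated=extrapolated,
    )
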