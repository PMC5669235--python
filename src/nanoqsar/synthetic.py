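"""Synthetic nanoparticle panels and raw assay plates with known ground
truth.

The generator emulates the statistical structure of the bundled study: three
topology classes whose mean EC50 follows a per-topology polynomial surface
in one descriptor (size midpoint for pure and core-shell particles, BET
surface for alloys), descriptors spanning the bundled panel's ranges, EC50
noise additive Gaussian (truncated below at 1 µg/mL), nine-point twofold
viability series from 1.56-300 µg/mL with multiplicative (lognormal)
readout noise, and twofold-dilution MIC plates. Every generator is a pure
function of (spec, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import ModelingTable, SplitStatus, Topology
from .dose_response import CHO_CONCENTRATIONS, four_pl
from .topology import TOPOLOGY_DESCRIPTOR, selected_fits

logger = logging.getLogger("nanoqsar")

#: floor for generated EC50 values, µg/mL
_EC50_FLOOR = 1.0


def default_truth_surfaces() -> dict[Topology, np.ndarray]:
    """Per-topology polynomial coefficients refit from the bundled panel
    (reporting variant), making the synthetic world a stand-in for the
    study's dose-response landscape."""
    from .dataset import bundled_modeling_table

    fits = selected_fits(bundled_modeling_table(variant="table1"))
    return {topo: fit.coefficients for topo, fit in fits.items()}


@dataclass
class SyntheticPanelSpec:
    """Ground-truth description of a synthetic panel.

    Defaults mirror the bundled study: 6/5/6 samples per topology, BET in
    136-182 m2/g, sizes within the panel's observed spans, additive EC50
    noise of 10 µg/mL and 5% multiplicative assay noise.
    """

    n_per_topology: dict[Topology, int] = field(default_factory=lambda: {
        Topology.PURE: 6, Topology.ALLOY: 5, Topology.CORE_SHELL: 6,
    })
    bet_range: tuple[float, float] = (136.0, 182.0)
    size_min_range: tuple[float, float] = (3.0, 63.0)
    size_max_range: tuple[float, float] = (4.5, 200.0)
    truth_surfaces: dict[Topology, np.ndarray] | None = None
    noise_sd: float = 10.0          # µg/mL, additive on EC50
    assay_noise_cv: float = 0.05    # multiplicative, on viability readouts
    seed: int = 0

    def __post_init__(self):
        for lo, hi in (self.bet_range, self.size_min_range, self.size_max_range):
            if not lo < hi:
                raise ValueError("descriptor ranges must be nonempty (lo < hi)")
        if self.noise_sd < 0 or self.assay_noise_cv < 0:
            raise ValueError("noise parameters must be nonnegative")

    def surfaces(self) -> dict[Topology, np.ndarray]:
        return (self.truth_surfaces if self.truth_surfaces is not None
                else default_truth_surfaces())


def _surface_range(spec: SyntheticPanelSpec, topo: Topology) -> tuple[float, float]:
    if TOPOLOGY_DESCRIPTOR[topo] == "bet_surface":
        return spec.bet_range
    lo = (spec.size_min_range[0] + spec.size_max_range[0]) / 2.0
    hi = (spec.size_min_range[1] + spec.size_max_range[1]) / 2.0
    return lo, hi


def _validate_surfaces(spec: SyntheticPanelSpec) -> None:
    for topo, coeffs in spec.surfaces().items():
        lo, hi = _surface_range(spec, topo)
        grid = np.linspace(lo, hi, 200)
        frac_bad = float(np.mean(np.polyval(coeffs, grid) <= 0))
        if frac_bad > 0.10:
            raise ValueError(
                f"truth surface for {topo.value} nonpositive over "
                f"{frac_bad:.0%} of the descriptor range"
            )


def generate_panel(spec: SyntheticPanelSpec) -> tuple[ModelingTable, np.ndarray]:
    """Draw a synthetic panel; returns (modeling table, noiseless EC50).

    Descriptors are uniform within the spec ranges (size_min <= size_max
    enforced by construction), EC50 is the topology surface evaluated at the
    paired descriptor plus truncated Gaussian noise, and the train/test split
    mimics the bundled proportions (~70% training, 5 bagging flags).
    """
    _validate_surfaces(spec)
    rng = np.random.default_rng(spec.seed)
    surfaces = spec.surfaces()
    labels, topos, bets, smins, smaxs, truths = [], [], [], [], [], []
    for topo in (Topology.PURE, Topology.ALLOY, Topology.CORE_SHELL):
        n = spec.n_per_topology.get(topo, 0)
        for i in range(n):
            bet = rng.uniform(*spec.bet_range)
            smin = rng.uniform(*spec.size_min_range)
            smax = rng.uniform(max(smin, spec.size_max_range[0]),
                               spec.size_max_range[1])
            desc = bet if TOPOLOGY_DESCRIPTOR[topo] == "bet_surface" \
                else (smin + smax) / 2.0
            truth = float(np.polyval(surfaces[topo], desc))
            labels.append(f"syn_{topo.value}_{i}")
            topos.append(topo)
            bets.append(bet); smins.append(smin); smaxs.append(smax)
            truths.append(truth)
    truths = np.array(truths)
    noisy = truths + rng.normal(0.0, spec.noise_sd, size=truths.size) \
        if spec.noise_sd > 0 else truths.copy()
    noisy = np.maximum(noisy, _EC50_FLOOR)
    n = len(labels)
    # split mimicking the bundled proportions: 12/17 train (5 bagging), 5/17 test
    n_test = max(1, round(n * 5 / 17))
    n_bag = min(max(1, round(n * 5 / 17)), n - n_test - 1)
    order = rng.permutation(n)
    statuses = [SplitStatus.TRAINING] * n
    for i in order[:n_test]:
        statuses[i] = SplitStatus.TEST
    for i in order[n_test:n_test + n_bag]:
        statuses[i] = SplitStatus.TRAINING_BAGGING
    table = ModelingTable(
        labels=labels, topology=topos, bet_surface=np.array(bets),
        size_min=np.array(smins), size_max=np.array(smaxs),
        ec50=noisy, split_status=statuses, ec50_variant="synthetic",
    )
    return table, truths


def generate_plate(
    true_ec50: float,
    hill: float = 1.5,
    top: float = 100.0,
    bottom: float = 0.0,
    concentrations: np.ndarray | None = None,
    cv: float = 0.05,
    replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic viability plate in the long CSV dialect
    (``concentration,replicate,od``; concentration-0 rows are controls).

    Viability follows the 4PL curve times lognormal noise of the given CV
    (unit mean); optical densities are against a unit control.
    """
    if cv < 0:
        raise ValueError("cv must be nonnegative")
    conc = CHO_CONCENTRATIONS if concentrations is None \
        else np.asarray(concentrations, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(cv ** 2))

    def noise(size):
        if cv == 0:
            return np.ones(size)
        return rng.lognormal(mean=-sigma ** 2 / 2.0, sigma=sigma, size=size)

    rows = []
    control_od = 1.0
    for rep in range(1, replicates + 1):
        rows.append((0.0, rep, control_od * noise(1)[0]))
    viab = four_pl(conc, bottom, top, true_ec50, hill)
    for c, v in zip(conc, viab):
        for rep, eps in enumerate(noise(replicates), start=1):
            rows.append((float(c), rep, v / 100.0 * control_od * eps))
    return pd.DataFrame(rows, columns=["concentration", "replicate", "od"])


def generate_mic_plate(
    true_mic: float | None,
    max_conc: float = 500.0,
    n_dilutions: int = 8,
    replicates: int = 3,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Synthetic twofold-dilution turbidity plate.

    Returns (concentrations descending, OD matrix conc x replicate, growth
    control OD). Wells at or above ``true_mic`` show >= 80% turbidity
    decrease; wells below (or all wells when ``true_mic`` is None) show
    growth. A ``true_mic`` off the dilution grid is snapped up (warning).
    """
    if max_conc <= 0:
        raise ValueError("max_conc must be positive")
    conc = max_conc / 2.0 ** np.arange(n_dilutions)
    rng = np.random.default_rng(seed)
    control_od = 1.0
    if true_mic is not None:
        if true_mic > max_conc:
            true_mic = None     # effect never reached on this plate
        else:
            grid_hits = conc[conc >= true_mic]
            snapped = float(grid_hits.min())
            if not np.isclose(snapped, true_mic, rtol=1e-9):
                logger.warning(
                    "true MIC %.4g not on the dilution grid; snapped up to %.4g",
                    true_mic, snapped,
                )
            true_mic = snapped
    od = np.empty((n_dilutions, replicates))
    for i, c in enumerate(conc):
        if true_mic is not None and c >= true_mic:
            decrease = rng.uniform(0.85, 0.99, size=replicates)
        else:
            decrease = rng.uniform(0.0, 0.30, size=replicates)
        od[i] = control_od * (1.0 - decrease)
    return conc, od, control_od
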