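"""Bundled nanoparticle panel, modeling-table construction, and panel CSV I/O.

The package ships the canonical study panel: 18 TiO2-based samples (one
unmodified control and 17 samples surface-modified with Au and/or Pd
nanoclusters) with cytotoxicity endpoints toward CHO-K1 cells (EC50, µg/mL),
antibacterial endpoints toward E. coli (MIC, inhibition-zone diameter), and
physicochemical descriptors (BET specific surface area, minimal/maximal
particle size from TEM).

The panel carries *two* observed-EC50 assignments, selected by the
``variant`` argument of :func:`build_modeling_table`:

* ``table1`` — the assignment of the summary toxicity table (default for
  reporting);
* ``table3`` — the assignment of the modeling table that also defines the
  training/test split (default for modeling).

The two assignments disagree for exactly three pairs of sample labels (the
EC50 values are swapped within each pair); both are bundled verbatim and the
choice is always explicit.
"""

from __future__ import annotations

import csv
import enum
import hashlib
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("nanoqsar")

#: sha256 checksums of the canonical bundled files; asserted on every load so
#: that silent edits of the shipped panel cannot go unnoticed.
PANEL_SHA256 = "abcb29cda1ad762310e1fbcb6fa3fd53fefcb1d05dfee523e4d0128a55e80044"
SPLIT_SHA256 = "efe57735439ca6d9a50547c66ab7af582ed927a46fb742e81fcaa69d9b907a17"

PANEL_COLUMNS = [
    "label", "topology", "bet_surface", "size_min", "size_max",
    "ec50", "ec50_sd", "mic", "zone_mm",
]

#: Disc diameter in the agar diffusion assay; a zone equal to it means no
#: inhibition.
DISC_DIAMETER_MM = 6.0


class Topology(str, enum.Enum):
    """Structural class of the metal load on the TiO2 support."""

    UNMODIFIED = "unmodified"
    PURE = "pure"          # monometallic Au or Pd clusters
    ALLOY = "alloy"        # intermixed bimetallic Au/Pd clusters
    CORE_SHELL = "core_shell"  # one metal coating the other


class SplitStatus(str, enum.Enum):
    TRAINING = "training"
    TRAINING_BAGGING = "training_bagging"
    TEST = "test"


class Censored:
    """A censored endpoint such as ``">300"``: the effect was not reached up
    to the stated bound, so the value is a lower bound, not a number."""

    __slots__ = ("bound",)

    def __init__(self, bound: float):
        self.bound = float(bound)

    def __repr__(self) -> str:
        return f">{self.bound:g}"

    def __eq__(self, other) -> bool:
        return isinstance(other, Censored) and other.bound == self.bound

    def __hash__(self) -> int:
        return hash(("Censored", self.bound))


def _parse_endpoint(text: str) -> float | Censored | None:
    text = text.strip()
    if not text:
        return None
    if text.startswith(">"):
        return Censored(float(text[1:]))
    return float(text)


def _format_endpoint(value: float | Censored | None) -> str:
    if value is None:
        return ""
    if isinstance(value, Censored):
        return f">{value.bound:g}"
    return format(value, "g")


@dataclass(frozen=True)
class NanoparticleRecord:
    """One sample: identity, topology, descriptors, and toxicity endpoints."""

    label: str
    topology: Topology
    bet_surface: float          # m2/g
    size_min: float             # nm
    size_max: float             # nm
    ec50: float | Censored | None = None      # µg/mL
    ec50_sd: float | None = None               # µg/mL
    mic: float | Censored | None = None        # µg/mL
    zone_mm: float | None = None               # mm
    bet_uncertainty: float = 5.0               # m2/g, ±5 throughout the panel

    def __post_init__(self):
        if self.size_min > self.size_max:
            raise ValueError(
                f"{self.label}: size_min ({self.size_min}) > size_max ({self.size_max})"
            )
        if self.bet_surface <= 0:
            raise ValueError(f"{self.label}: BET surface must be positive")
        if isinstance(self.ec50, float) and self.ec50 <= 0:
            raise ValueError(f"{self.label}: finite EC50 must be positive")
        if self.zone_mm is not None and self.zone_mm < DISC_DIAMETER_MM:
            raise ValueError(
                f"{self.label}: inhibition zone below the {DISC_DIAMETER_MM} mm disc"
            )

    @property
    def average_size(self) -> float:
        """Midpoint of the measured size interval, nm."""
        return (self.size_min + self.size_max) / 2.0

    @property
    def ec50_censored(self) -> bool:
        return isinstance(self.ec50, Censored)


class PanelSchemaError(ValueError):
    """A user panel CSV violates the documented schema."""


def _bundled_path(name: str) -> Path:
    return Path(resources.files("nanoqsar").joinpath("data", name))  # type: ignore[arg-type]


def _verify_checksum(path: Path, expected: str) -> str:
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    if digest != expected:
        raise RuntimeError(
            f"bundled file {path.name} is corrupted: sha256 {digest} != {expected}"
        )
    return digest


def load_bundled_dataset() -> list[NanoparticleRecord]:
    """Load the canonical 18-sample panel shipped with the package.

    Every printed endpoint is preserved to its printed precision; censored
    endpoints (EC50 ``">300"`` of the unmodified control, MIC ``">500"`` of
    every sample) stay censored.
    """
    path = _bundled_path("tio2_panel.csv")
    _verify_checksum(path, PANEL_SHA256)
    return read_panel_csv(path)


def dataset_checksum() -> str:
    """sha256 of the canonical bundled panel file."""
    return _verify_checksum(_bundled_path("tio2_panel.csv"), PANEL_SHA256)


def read_panel_csv(path: str | Path) -> list[NanoparticleRecord]:
    """Read a panel CSV (schema: ``label,topology,bet_surface,size_min,
    size_max,ec50,ec50_sd,mic,zone_mm`` plus optional ``bet_uncertainty``).

    Censored endpoints are written as ``">NUMBER"`` strings. Malformed rows
    are reported with their line number.
    """
    path = Path(path)
    records: list[NanoparticleRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in PANEL_COLUMNS if c not in header]
        if missing:
            raise PanelSchemaError(
                f"{path}: missing required column(s): {', '.join(missing)}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(
                    NanoparticleRecord(
                        label=row["label"].strip(),
                        topology=Topology(row["topology"].strip()),
                        bet_surface=float(row["bet_surface"]),
                        size_min=float(row["size_min"]),
                        size_max=float(row["size_max"]),
                        ec50=_parse_endpoint(row["ec50"]),
                        ec50_sd=(float(row["ec50_sd"]) if row["ec50_sd"].strip() else None),
                        mic=_parse_endpoint(row["mic"]),
                        zone_mm=(float(row["zone_mm"]) if row["zone_mm"].strip() else None),
                        bet_uncertainty=float(row.get("bet_uncertainty") or 5.0),
                    )
                )
            except (ValueError, KeyError) as exc:
                raise PanelSchemaError(f"{path}, line {lineno}: {exc}") from exc
    return records


def write_panel_csv(path: str | Path, records: Iterable[NanoparticleRecord]) -> None:
    """Write records in the panel CSV dialect; lossless round trip with
    :func:`read_panel_csv`, including censored markers."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(PANEL_COLUMNS + ["bet_uncertainty"])
        for r in records:
            writer.writerow([
                r.label, r.topology.value, format(r.bet_surface, "g"),
                format(r.size_min, "g"), format(r.size_max, "g"),
                _format_endpoint(r.ec50),
                "" if r.ec50_sd is None else format(r.ec50_sd, "g"),
                _format_endpoint(r.mic),
                "" if r.zone_mm is None else format(r.zone_mm, "g"),
                format(r.bet_uncertainty, "g"),
            ])


# ---------------------------------------------------------------------------
# Modeling table
# ---------------------------------------------------------------------------

#: Descriptor columns used by the Gaussian-process model, in order.
GP_DESCRIPTORS = ("bet_surface", "size_min", "size_max")


def _load_split_table() -> pd.DataFrame:
    path = _bundled_path("modeling_split.csv")
    _verify_checksum(path, SPLIT_SHA256)
    return pd.read_csv(path)


@dataclass
class ModelingTable:
    """The 17 finite-EC50 samples arranged for modeling.

    ``ec50`` holds the *active* observed values for the selected variant;
    the training/test split is variant-independent.
    """

    labels: list[str]
    topology: list[Topology]
    bet_surface: np.ndarray
    size_min: np.ndarray
    size_max: np.ndarray
    ec50: np.ndarray
    split_status: list[SplitStatus]
    ec50_variant: str = "table3"

    def __post_init__(self):
        n = len(self.labels)
        for name in ("topology", "split_status"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != number of labels")
        for name in ("bet_surface", "size_min", "size_max", "ec50"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must be a length-{n} vector")
            setattr(self, name, arr)

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def average_size(self) -> np.ndarray:
        return (self.size_min + self.size_max) / 2.0

    @property
    def training_mask(self) -> np.ndarray:
        return np.array([s != SplitStatus.TEST for s in self.split_status])

    @property
    def bagging_mask(self) -> np.ndarray:
        return np.array([s == SplitStatus.TRAINING_BAGGING for s in self.split_status])

    @property
    def test_mask(self) -> np.ndarray:
        return ~self.training_mask

    def descriptor_matrix(self) -> np.ndarray:
        """(n, 3) matrix of the GP descriptors (BET, size_min, size_max)."""
        return np.column_stack([self.bet_surface, self.size_min, self.size_max])

    def subset(self, mask: np.ndarray) -> "ModelingTable":
        idx = np.flatnonzero(mask)
        return ModelingTable(
            labels=[self.labels[i] for i in idx],
            topology=[self.topology[i] for i in idx],
            bet_surface=self.bet_surface[idx],
            size_min=self.size_min[idx],
            size_max=self.size_max[idx],
            ec50=self.ec50[idx],
            split_status=[self.split_status[i] for i in idx],
            ec50_variant=self.ec50_variant,
        )

    def with_ec50(self, ec50: np.ndarray) -> "ModelingTable":
        out = ModelingTable(
            labels=list(self.labels), topology=list(self.topology),
            bet_surface=self.bet_surface.copy(), size_min=self.size_min.copy(),
            size_max=self.size_max.copy(), ec50=np.asarray(ec50, float).copy(),
            split_status=list(self.split_status), ec50_variant=self.ec50_variant,
        )
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "label": self.labels,
            "topology": [t.value for t in self.topology],
            "bet_surface": self.bet_surface,
            "size_min": self.size_min,
            "size_max": self.size_max,
            "average_size": self.average_size,
            "ec50": self.ec50,
            "status": [s.value for s in self.split_status],
        })


def build_modeling_table(
    records: Sequence[NanoparticleRecord],
    variant: str = "table3",
) -> ModelingTable:
    """Arrange the finite-EC50 records for modeling.

    Parameters
    ----------
    records
        Panel records; censored-EC50 samples are excluded (logged).
    variant
        ``"table1"`` keeps each record's own EC50; ``"table3"`` reassigns
        observed EC50 values to labels as in the bundled modeling table.
        The train/test split always follows the bundled modeling table and
        requires the bundled label set.
    """
    if variant not in ("table1", "table3"):
        raise ValueError(f"unknown EC50 variant: {variant!r}")
    kept = []
    for r in records:
        if isinstance(r.ec50, Censored) or r.ec50 is None:
            logger.info("excluding %s from modeling (censored/missing EC50)", r.label)
            continue
        kept.append(r)
    split = _load_split_table().set_index("label")
    unknown = [r.label for r in kept if r.label not in split.index]
    if unknown:
        raise ValueError(
            "records not in the bundled modeling split (user panels have no "
            f"canonical split): {', '.join(unknown)}"
        )
    # keep the modeling-table row order
    order = [lab for lab in split.index if lab in {r.label for r in kept}]
    by_label = {r.label: r for r in kept}
    recs = [by_label[lab] for lab in order]
    if variant == "table3":
        ec50 = np.array([split.loc[r.label, "observed_ec50"] for r in recs])
    else:
        ec50 = np.array([float(r.ec50) for r in recs])
    return ModelingTable(
        labels=[r.label for r in recs],
        topology=[r.topology for r in recs],
        bet_surface=np.array([r.bet_surface for r in recs]),
        size_min=np.array([r.size_min for r in recs]),
        size_max=np.array([r.size_max for r in recs]),
        ec50=ec50,
        split_status=[SplitStatus(split.loc[r.label, "status"]) for r in recs],
        ec50_variant=variant,
    )


def bundled_modeling_table(variant: str = "table3") -> ModelingTable:
    """Convenience: :func:`load_bundled_dataset` + :func:`build_modeling_table`."""
    return build_modeling_table(load_bundled_dataset(), variant=variant)


def bundled_reference_predictions() -> pd.DataFrame:
    """The bundled modeling table's printed predicted/error columns
    (label, status, observed_ec50, predicted_ec50, bagging_predicted_ec50,
    prediction_error)."""
    return _load_split_table()
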