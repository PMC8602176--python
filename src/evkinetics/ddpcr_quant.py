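"""Droplet digital PCR quantification and batch normalization.

ddPCR partitions a reaction into ~20,000 droplets and scores each positive
or negative for the tracer-miRNA amplicon.  Absolute copy numbers follow
from Poisson statistics on the positive fraction.  Copy numbers are then
normalized across batches with per-batch high/low standards against a
reference standard curve, converted to EV-protein concentration using each
animal's dose aliquot, and screened with a negative-control QC rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "DropletWell",
    "StandardCurve",
    "BatchQuantRecord",
    "poisson_copies",
    "fit_standard_curve",
    "normalize_batch",
    "copies_to_ev_concentration",
    "qc_negative_control",
    "NEGATIVE_CONTROL_THRESHOLD",
    "DEFAULT_DROPLET_VOLUME_NL",
]

#: Negative-control copy number above which a sample set is flagged for
#: reanalysis (strictly greater than).
NEGATIVE_CONTROL_THRESHOLD = 200.0

#: Nominal droplet volume, nL (vendor convention; configurable per well).
DEFAULT_DROPLET_VOLUME_NL = 0.85


@dataclass(frozen=True)
class DropletWell:
    """One ddPCR well: droplet counts plus the volumes that set the scale."""

    n_positive: int
    n_total: int
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL
    reaction_volume_ul: float = 20.0

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValueError("well has no droplets")
        if not 0 <= self.n_positive <= self.n_total:
            raise ValueError("need 0 <= n_positive <= n_total")
        if self.droplet_volume_nl <= 0 or self.reaction_volume_ul <= 0:
            raise ValueError("volumes must be > 0")


def poisson_copies(well: DropletWell) -> float:
    """Copies per reaction from the positive-droplet fraction.

    With template molecules Poisson-distributed over droplets, the mean
    copies per droplet is lambda = -ln(1 - p) where p is the positive
    fraction; copies per reaction scale by reaction volume over droplet
    volume.  A fully saturated well carries no information (lambda
    diverges) and raises.
    """
    if well.n_positive == well.n_total:
        raise ValueError(
            f"all {well.n_total} droplets positive: saturated well, copy number undefined"
        )
    lam = -math.log1p(-well.n_positive / well.n_total)
    droplet_volumes_per_reaction = well.reaction_volume_ul * 1000.0 / well.droplet_volume_nl
    return lam * droplet_volumes_per_reaction


@dataclass(frozen=True)
class StandardCurve:
    """Linear reference curve: copies per reaction vs. concentration factor.

    Built from serial dilutions of the high standard (factors ~0.001 to 5).
    ``reference_high``/``reference_low`` are the fitted copy numbers at
    factors 1 and 1/30, the anchors used for batch normalization.
    """

    slope: float
    intercept: float
    points: tuple[tuple[float, float], ...] = ()

    def predict(self, factor: float) -> float:
        return self.intercept + self.slope * factor

    @property
    def reference_high(self) -> float:
        return self.predict(1.0)

    @property
    def reference_low(self) -> float:
        return self.predict(1.0 / 30.0)


def fit_standard_curve(points: Sequence[tuple[float, float]]) -> StandardCurve:
    """Ordinary least squares of copies on concentration factor."""
    pts = [(float(f), float(c)) for f, c in points]
    factors = np.array([p[0] for p in pts])
    copies = np.array([p[1] for p in pts])
    if len(set(factors.tolist())) < 2:
        raise ValueError("standard curve requires >= 2 distinct concentration factors")
    X = np.column_stack([np.ones_like(factors), factors])
    (intercept, slope), *_ = np.linalg.lstsq(X, copies, rcond=None)
    return StandardCurve(slope=float(slope), intercept=float(intercept), points=tuple(pts))


@dataclass
class BatchQuantRecord:
    """Measurements for one batch (one set of samples run together).

    Every batch carries its own high and low standards; ``sample_copies``
    maps (animal id, time in minutes) to raw copies per reaction.
    ``dose_aliquot_copies_per_ug`` is the batch's assay of the reserved
    dose aliquot, copies per microgram of EV protein, which anchors the
    conversion from copy number to protein concentration.
    """

    batch_id: str
    high_standard_copies: float
    low_standard_copies: float
    sample_copies: dict[tuple[str, float], float]
    negative_control_copies: float
    dose_aliquot_copies_per_ug: float
    dilution_factors: tuple[float, ...] = (1.0,)
    plasma_volume_ml: float = 0.05

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.dilution_factors):
            raise ValueError("dilution factors must be > 0")
        if self.plasma_volume_ml <= 0:
            raise ValueError("plasma volume must be > 0")


def normalize_batch(
    record: BatchQuantRecord,
    curve: StandardCurve,
    method: str = "affine",
) -> dict[tuple[str, float], float]:
    """Map batch sample copies onto the reference-standard scale.

    The affine map sends (batch low, batch high) -> (reference low,
    reference high), correcting both multiplicative batch efficiency and
    additive background; ``method="scale"`` uses only the high standard
    (pure rescaling).
    """
    if method not in ("affine", "scale"):
        raise ValueError(f"unknown normalization method {method!r}")
    bh, bl = record.high_standard_copies, record.low_standard_copies
    if method == "scale":
        if bh <= 0:
            raise ValueError(f"batch {record.batch_id}: nonpositive high standard")
        scale = curve.reference_high / bh
        return {k: v * scale for k, v in record.sample_copies.items()}
    if bh == bl:
        raise ValueError(f"batch {record.batch_id}: degenerate standards (high == low)")
    slope = (curve.reference_high - curve.reference_low) / (bh - bl)
    return {
        k: curve.reference_low + (v - bl) * slope for k, v in record.sample_copies.items()
    }


def copies_to_ev_concentration(
    normalized_copies: Mapping[tuple[str, float], float],
    record: BatchQuantRecord,
) -> dict[tuple[str, float], float]:
    """Convert normalized copies to EV protein concentration (ug/mL plasma).

    concentration = copies * product(dilution factors)
                    / (dose-aliquot copies per ug) / (assayed plasma volume).
    Normalizing against each animal's own dose aliquot absorbs differences
    in tracer loading between cell lines and EV preparations.
    """
    if record.dose_aliquot_copies_per_ug <= 0:
        raise ValueError(f"batch {record.batch_id}: missing or nonpositive dose aliquot")
    dilution = math.prod(record.dilution_factors)
    denom = record.dose_aliquot_copies_per_ug * record.plasma_volume_ml
    return {k: v * dilution / denom for k, v in normalized_copies.items()}


def qc_negative_control(negative_control_copies: float) -> bool:
    """True if the batch passes QC (negative control <= threshold of 200 copies).

    Flagged batches (False) are marked for reanalysis or exclusion; the
    threshold is strict, so exactly 200 copies passes.
    """
    if negative_control_copies < 0:
        raise ValueError("copy numbers cannot be negative")
    return negative_control_copies <= NEGATIVE_CONTROL_THRESHOLD
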