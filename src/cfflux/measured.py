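"""Measured per-cell-type plasma cfDNA concentrations and detectability.

The total plasma cfDNA concentration is first corrected for single-strand
ultrashort (~50 bp) fragments that standard library preparations miss: the
correction factor is only known to lie between 1 (no effect) and 2 (doubling),
so it is folded in as a uniform distribution by bootstrap and refit.  The
adjusted total is then apportioned to cell types using methylome-deconvolution
fractions, and each potential concentration is classified against the assay
sensitivity band.
"""

from __future__ import annotations

import enum

from .flux import PhysiologicalConstants
from .uncertainty import LognormalQuantity, apply_uniform_factor, multiply

__all__ = [
    "DetectionStatus",
    "adjusted_total",
    "celltype_concentration",
    "detection_status",
]


class DetectionStatus(str, enum.Enum):
    """Where a potential concentration falls relative to assay sensitivity."""

    ABOVE_DECONVOLUTION = "above_deconvolution"  #: detectable by genome-wide deconvolution
    TARGETED_ONLY = "targeted_only"  #: needs a targeted cell-type marker assay
    BELOW_DETECTION = "below_detection"  #: below all current assays


def adjusted_total(
    total: LognormalQuantity,
    constants: PhysiologicalConstants,
    seed: int,
    n_iter: int = 10_000,
) -> LognormalQuantity:
    """Total cfDNA corrected for ultrashort fragments.

    Applies the uniform adjustment range from ``constants`` (default 1-2,
    expected multiplier 1.5) via
    :func:`~cfflux.uncertainty.apply_uniform_factor`.
    """
    lo, hi = constants.adjustment_range
    return apply_uniform_factor(total, lo, hi, n_iter=n_iter, seed=seed)


def celltype_concentration(
    total_adjusted: LognormalQuantity, fraction: LognormalQuantity
) -> LognormalQuantity:
    """Concentration attributed to one cell type: adjusted total x fraction."""
    if not (0 < fraction.median <= 1):
        raise ValueError(
            f"deconvolution fraction must be in (0, 1], got {fraction.median}"
        )
    return multiply(total_adjusted, fraction)


def detection_status(
    potential: LognormalQuantity, constants: PhysiologicalConstants
) -> DetectionStatus:
    """Classify a potential concentration against the sensitivity band.

    The comparison uses the median: the detection limit is a gradient across
    assay designs, so the classifier reports which band the point estimate
    falls in.
    """
    lo, hi = constants.detection_band
    if potential.median >= hi:
        return DetectionStatus.ABOVE_DECONVOLUTION
    if potential.median >= lo:
        return DetectionStatus.TARGETED_ONLY
    return DetectionStatus.BELOW_DETECTION
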