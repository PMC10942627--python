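"""Potential plasma cfDNA concentration from cellular turnover.

The mass balance: if every genome of every dying cell reached the plasma and
cleared with mean lifetime tau, the standing plasma concentration of that
cell type's DNA would be

    X_c = d_c * p_c * tau / V_plasma        [genome equivalents / ml]

with d_c the turnover (cells/day), p_c the ploidy (haploid genome sets per
dying cell), tau the mean cfDNA lifetime and V_plasma the plasma volume.
Internally everything is evaluated in days and millilitres; GE/ml converts
to g/ml through the haploid genome mass m_h.

Inverting the same balance against a *measured* concentration yields the
clearance half-life the systemic-clearance hypothesis would require — a
diagnostic used to argue that most dying-cell DNA never enters the blood.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

from .turnover import CellTypeRecord
from .uncertainty import LognormalQuantity, divide, from_interval, make_lognormal, multiply

__all__ = [
    "PhysiologicalConstants",
    "default_constants",
    "default_total_cfdna",
    "default_lifetime",
    "potential_cfdna",
    "to_mass_concentration",
    "implied_halflife",
]

HOURS_PER_DAY = 24.0
SECONDS_PER_DAY = 86_400.0
ML_PER_L = 1000.0


def default_lifetime() -> LognormalQuantity:
    """Mean plasma cfDNA lifetime, hours.

    The median 0.7 h corresponds to a clearance half-life of ~29 min
    (tau = half-life / ln 2).  The error factor is derived from the
    literature half-life range of 15-120 min treated as an approximate 95%
    interval; half-life and mean lifetime share the same multiplicative
    spread.
    """
    return from_interval(0.7, 0.7 * 15 / 29.1, 0.7 * 120 / 29.1)


def default_total_cfdna() -> LognormalQuantity:
    """Total plasma cfDNA concentration in healthy adults, GE/ml.

    Median ~1000 genome equivalents/ml (cohort median of individuals under
    47 y).  Uncertainty combines the reported confidence interval of that
    median with inter-individual and analytical variation (sampling-time and
    assay precision), all expressed as multiplication error factors.
    """
    median_ci = from_interval(1000.0, 850.0, 1160.0)
    biological_variation = make_lognormal(1.0, 1.44)
    q = multiply(median_ci, biological_variation)
    return make_lognormal(1000.0, q.factor)


@dataclass(frozen=True)
class PhysiologicalConstants:
    """Physiological constants of the cfDNA mass balance.

    Attributes
    ----------
    plasma_volume_l
        Blood plasma volume, litres.
    mean_lifetime_h
        Mean plasma lifetime of a cfDNA molecule, hours (= half-life / ln 2),
        with multiplicative uncertainty.
    haploid_genome_mass_g
        Mass of one haploid genome, grams.
    total_cfdna
        Total plasma cfDNA concentration, GE/ml, with uncertainty.
    adjustment_range
        Uniform range of the ultrashort-fragment correction factor applied to
        the total concentration (single-strand ~50 bp fragments invisible to
        standard assays); midpoint 1.5.
    detection_band
        Assay sensitivity band, GE/ml: lower bound for targeted single-type
        marker assays, upper bound for genome-wide deconvolution.
    """

    plasma_volume_l: float = 3.0
    mean_lifetime_h: LognormalQuantity = field(default_factory=default_lifetime)
    haploid_genome_mass_g: float = 3.2e-12
    total_cfdna: LognormalQuantity = field(default_factory=default_total_cfdna)
    adjustment_range: tuple[float, float] = (1.0, 2.0)
    detection_band: tuple[float, float] = (1.0, 10.0)

    def __post_init__(self) -> None:
        if self.plasma_volume_l <= 0 or self.haploid_genome_mass_g <= 0:
            raise ValueError("physiological constants must be positive")
        for name in ("adjustment_range", "detection_band"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi):
                raise ValueError(f"{name} must satisfy 0 <= low <= high")

    @property
    def plasma_volume_ml(self) -> float:
        return self.plasma_volume_l * ML_PER_L

    @property
    def mean_lifetime_days(self) -> LognormalQuantity:
        return self.mean_lifetime_h.scaled(1.0 / HOURS_PER_DAY)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "plasma_volume_l": self.plasma_volume_l,
            "mean_lifetime_h": _q_dict(self.mean_lifetime_h),
            "haploid_genome_mass_g": self.haploid_genome_mass_g,
            "total_cfdna_ge_per_ml": _q_dict(self.total_cfdna),
            "adjustment_range": list(self.adjustment_range),
            "detection_band": list(self.detection_band),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PhysiologicalConstants":
        payload = json.loads(Path(path).read_text())
        return cls(
            plasma_volume_l=payload["plasma_volume_l"],
            mean_lifetime_h=_q_parse(payload["mean_lifetime_h"]),
            haploid_genome_mass_g=payload["haploid_genome_mass_g"],
            total_cfdna=_q_parse(payload["total_cfdna_ge_per_ml"]),
            adjustment_range=tuple(payload["adjustment_range"]),
            detection_band=tuple(payload["detection_band"]),
        )


def _q_dict(q: LognormalQuantity) -> dict:
    return {"median": q.median, "factor": q.factor}


def _q_parse(d: dict) -> LognormalQuantity:
    return make_lognormal(d["median"], d.get("factor", 1.0))


def default_constants() -> PhysiologicalConstants:
    """Constants with the standard printed values (3 L, 0.7 h, 3.2 pg, ...)."""
    return PhysiologicalConstants()


def potential_cfdna(
    record: CellTypeRecord, constants: PhysiologicalConstants
) -> LognormalQuantity:
    """Potential cfDNA concentration X_c = d_c * p_c * tau / V_plasma, GE/ml.

    Uncertainty combines the turnover factor with the lifetime factor by the
    product rule; ploidy and plasma volume are treated as exact.
    """
    per_genome = record.ploidy / constants.plasma_volume_ml
    return multiply(record.turnover, constants.mean_lifetime_days).scaled(per_genome)


def to_mass_concentration(
    x: LognormalQuantity, constants: PhysiologicalConstants
) -> LognormalQuantity:
    """Convert GE/ml to g/ml by the haploid genome mass; factor unchanged."""
    return x.scaled(constants.haploid_genome_mass_g)


def implied_halflife(
    measured: LognormalQuantity,
    record: CellTypeRecord,
    constants: PhysiologicalConstants,
) -> LognormalQuantity:
    """Clearance half-life required if all dying-cell DNA entered the blood.

    Inverts the mass balance: tau_implied = measured * V_plasma /
    (d_c * p_c); returns the half-life tau_implied * ln 2 in seconds.
    Equivalently, half-life = (assumed half-life) * (measured / potential).
    """
    flux_per_ml = record.turnover.scaled(record.ploidy / constants.plasma_volume_ml)
    tau_days = divide(measured, flux_per_ml)
    return tau_days.scaled(math.log(2) * SECONDS_PER_DAY)
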