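"""Per-cell-type turnover table and the bespoke turnover estimators.

Most turnover rates (cells dying per day, ``d_c``) come straight from
published whole-body turnover estimates and enter the table as data.  Two
cell types need dedicated treatment:

* megakaryocytes — estimated two independent ways (marrow census divided by
  maturation time; platelet production divided by platelets produced per
  megakaryocyte) and merged with a disagreement-penalizing rule;
* hepatocytes — polyploid, so the turnover and an effective ploidy are
  obtained by combining cell counts and death rates across ploidy classes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .uncertainty import LognormalQuantity, bootstrap_sum, divide, make_lognormal

__all__ = [
    "CellTypeRecord",
    "PloidyGroup",
    "CellTypeTableError",
    "mk_turnover_from_marrow",
    "mk_turnover_from_platelets",
    "hepatocyte_turnover",
    "combine_estimates",
    "load_celltype_table",
    "save_celltype_table",
]

TABLE_COLUMNS = [
    "name",
    "turnover_median",
    "turnover_factor",
    "ploidy",
    "shed_externally",
    "fraction_median",
    "fraction_factor",
]


class CellTypeTableError(ValueError):
    """Raised when a cell-type CSV violates the table schema or invariants."""


@dataclass(frozen=True)
class CellTypeRecord:
    """One cell type: turnover, ploidy, shedding route, optional cfDNA fraction.

    Attributes
    ----------
    name
        Identifier, e.g. ``"erythrocyte_progenitors"``.
    turnover
        Cells dying per day (``d_c``), with multiplicative uncertainty.
    ploidy
        Haploid genome sets per dying cell (``p_c``); 2 for diploid somatic
        cells, higher for polyploid types such as megakaryocytes.
    shed_externally
        True for epithelia whose dying cells leave the body (gut, lung,
        kidney, bladder, skin); such cells contribute no plasma cfDNA and
        never carry a measured fraction.
    measured_fraction
        Fraction of total plasma cfDNA attributed to this cell type by
        methylome deconvolution, when profiled.
    """

    name: str
    turnover: LognormalQuantity
    ploidy: float = 2.0
    shed_externally: bool = False
    measured_fraction: Optional[LognormalQuantity] = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("cell type name must be non-empty")
        if self.ploidy < 1:
            raise ValueError(f"{self.name}: ploidy must be >= 1, got {self.ploidy}")
        if self.measured_fraction is not None:
            if not (0 < self.measured_fraction.median <= 1):
                raise ValueError(
                    f"{self.name}: measured fraction median must be in (0, 1], "
                    f"got {self.measured_fraction.median}"
                )
            if self.shed_externally:
                raise ValueError(
                    f"{self.name}: externally shed cell types cannot carry a "
                    "measured plasma cfDNA fraction"
                )


@dataclass(frozen=True)
class PloidyGroup:
    """A hepatocyte ploidy class: census size, death rate, and ploidy."""

    cell_count: float
    death_rate: float
    ploidy: float

    def __post_init__(self) -> None:
        if self.cell_count <= 0 or self.death_rate <= 0 or self.ploidy <= 0:
            raise ValueError("ploidy group fields must all be positive")
        if self.death_rate > 1:
            raise ValueError(f"death rate is a fraction/day, got {self.death_rate}")

    @property
    def flux(self) -> float:
        """Cells of this class dying per day."""
        return self.cell_count * self.death_rate


def mk_turnover_from_marrow(
    n_megakaryocytes: LognormalQuantity, maturation_time: LognormalQuantity
) -> LognormalQuantity:
    """Megakaryocyte turnover from the marrow census and maturation time.

    turnover [cells/day] = number in marrow / maturation time [days].
    """
    return divide(n_megakaryocytes, maturation_time)


def mk_turnover_from_platelets(
    platelet_production: LognormalQuantity, platelets_per_mk: LognormalQuantity
) -> LognormalQuantity:
    """Megakaryocyte turnover from platelet output.

    turnover [cells/day] = platelets produced per day / platelets per
    megakaryocyte.
    """
    return divide(platelet_production, platelets_per_mk)


def hepatocyte_turnover(
    groups: Sequence[PloidyGroup],
    flux_factor: float = 1.0,
    n_samples: int = 1000,
    seed: int = 0,
) -> tuple[LognormalQuantity, float]:
    """Combine hepatocyte ploidy classes into one turnover and effective ploidy.

    The turnover median is the summed death flux ``sum(count_i * rate_i)``.
    The effective ploidy is the death-flux-weighted mean ploidy, treated as
    exact.  When ``flux_factor > 1`` the same multiplicative uncertainty is
    attached to each group flux and propagated through the sum by
    :func:`~cfflux.uncertainty.bootstrap_sum`.
    """
    if not groups:
        raise ValueError("hepatocyte_turnover requires at least one ploidy group")
    fluxes = np.array([g.flux for g in groups])
    total = float(fluxes.sum())
    effective_ploidy = float(
        sum(g.flux * g.ploidy for g in groups) / total
    )
    if flux_factor == 1.0:
        return make_lognormal(total), effective_ploidy
    fitted = bootstrap_sum(
        [make_lognormal(f, flux_factor) for f in fluxes],
        n_samples=n_samples,
        seed=seed,
    )
    # keep the closed-form median; the bootstrap supplies only the shape
    return make_lognormal(total, fitted.factor), effective_ploidy


def combine_estimates(
    a: LognormalQuantity,
    b: LognormalQuantity,
    unit_a: Optional[str] = None,
    unit_b: Optional[str] = None,
) -> LognormalQuantity:
    """Merge two independent estimates of the same quantity.

    The merged median is the geometric mean; the merged factor is the larger
    of the within-estimate factors and the between-estimate spread factor
    ``sqrt(larger median / smaller median)``, so disagreement between the two
    methods widens the result rather than narrowing it.
    """
    if unit_a != unit_b:
        raise ValueError(f"cannot combine estimates with units {unit_a!r} and {unit_b!r}")
    geo = math.sqrt(a.median * b.median)
    spread = math.sqrt(max(a.median, b.median) / min(a.median, b.median))
    return LognormalQuantity(geo, max(a.factor, b.factor, spread))


def _parse_row(i: int, row: pd.Series) -> CellTypeRecord:
    try:
        frac = None
        if pd.notna(row["fraction_median"]) and str(row["fraction_median"]) != "":
            f_factor = row["fraction_factor"]
            frac = make_lognormal(
                float(row["fraction_median"]),
                float(f_factor) if pd.notna(f_factor) else 1.0,
            )
        shed = str(row["shed_externally"]).strip().lower() in ("true", "1", "yes")
        return CellTypeRecord(
            name=str(row["name"]),
            turnover=make_lognormal(
                float(row["turnover_median"]), float(row["turnover_factor"])
            ),
            ploidy=float(row["ploidy"]),
            shed_externally=shed,
            measured_fraction=frac,
        )
    except (ValueError, TypeError) as exc:
        raise CellTypeTableError(f"row {i}: {exc}") from exc


def load_celltype_table(path: str | Path) -> list[CellTypeRecord]:
    """Read and validate a cell-type CSV.

    The schema is ``name, turnover_median, turnover_factor, ploidy,
    shed_externally, fraction_median, fraction_factor`` (the last two may be
    empty).  Rows violating record invariants raise
    :class:`CellTypeTableError` with the offending row number; a header-only
    file yields an empty list with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise CellTypeTableError(f"{path}: missing columns {missing}")
    if df.empty:
        warnings.warn(f"{path}: cell-type table is empty", stacklevel=2)
        return []
    return [_parse_row(i + 2, row) for i, (_, row) in enumerate(df.iterrows())]


def save_celltype_table(records: Sequence[CellTypeRecord], path: str | Path) -> None:
    """Write records in the same CSV schema read by :func:`load_celltype_table`."""
    rows = []
    for r in records:
        # repr() gives shortest-roundtrip float formatting, so load(save(x)) == x
        rows.append(
            {
                "name": r.name,
                "turnover_median": repr(float(r.turnover.median)),
                "turnover_factor": repr(float(r.turnover.factor)),
                "ploidy": repr(float(r.ploidy)),
                "shed_externally": "true" if r.shed_externally else "false",
                "fraction_median": (
                    repr(float(r.measured_fraction.median)) if r.measured_fraction else ""
                ),
                "fraction_factor": (
                    repr(float(r.measured_fraction.factor)) if r.measured_fraction else ""
                ),
            }
        )
    pd.DataFrame(rows, columns=TABLE_COLUMNS).to_csv(path, index=False)
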