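"""Capture ratios: what fraction of dying-cell DNA shows up as plasma cfDNA.

For each profiled cell type the capture ratio is measured / potential
concentration — the fraction of the DNA of dying cells that appears in plasma
as measurable cfDNA.  The headline summaries are the largest ratio (an upper
bound on capture efficiency), the fold-range of ratios across cell types, and
per-type 95% confidence intervals from the propagated lognormal shapes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .flux import PhysiologicalConstants, potential_cfdna
from .measured import DetectionStatus, adjusted_total, celltype_concentration, detection_status
from .turnover import CellTypeRecord
from .uncertainty import LognormalQuantity, ci95, divide

__all__ = [
    "FluxResult",
    "cfdna_ratio",
    "summarize",
    "fold_range",
    "max_capture_fraction",
    "results_to_dataframe",
    "write_results",
]


@dataclass(frozen=True)
class FluxResult:
    """Mass-balance summary for one cell type.

    ``measured`` and ``ratio`` are present only for cell types profiled by
    deconvolution; externally shed types carry a potential concentration
    only.
    """

    name: str
    potential: LognormalQuantity
    measured: Optional[LognormalQuantity]
    ratio: Optional[LognormalQuantity]
    ci95_ratio: Optional[tuple[float, float]]
    detection: DetectionStatus
    shed_externally: bool = False

    def __post_init__(self) -> None:
        if (self.measured is None) != (self.ratio is None):
            raise ValueError(f"{self.name}: ratio must be present iff measured is")
        if self.ratio is not None:
            expected = self.measured.median / self.potential.median
            if not np.isclose(self.ratio.median, expected, rtol=1e-9):
                raise ValueError(
                    f"{self.name}: ratio median {self.ratio.median} inconsistent "
                    f"with measured/potential {expected}"
                )


def cfdna_ratio(
    measured: LognormalQuantity, potential: LognormalQuantity
) -> LognormalQuantity:
    """Dimensionless capture ratio measured / potential."""
    return divide(measured, potential)


def summarize(
    records: Sequence[CellTypeRecord],
    constants: PhysiologicalConstants,
    seed: int,
    n_adjust: int = 10_000,
) -> list[FluxResult]:
    """Run the full mass balance over a cell-type table.

    The total cfDNA concentration is adjusted once (ultrashort-fragment
    correction, seeded), then each record gets a potential concentration;
    records with deconvolution fractions additionally get a measured
    concentration, capture ratio and 95% CI.  Output is sorted by descending
    turnover median.
    """
    total_adj = adjusted_total(constants.total_cfdna, constants, seed=seed, n_iter=n_adjust)
    results = []
    for rec in sorted(records, key=lambda r: -r.turnover.median):
        pot = potential_cfdna(rec, constants)
        measured = ratio = interval = None
        if rec.measured_fraction is not None:
            measured = celltype_concentration(total_adj, rec.measured_fraction)
            ratio = cfdna_ratio(measured, pot)
            interval = ci95(ratio)
        results.append(
            FluxResult(
                name=rec.name,
                potential=pot,
                measured=measured,
                ratio=ratio,
                ci95_ratio=interval,
                detection=detection_status(pot, constants),
                shed_externally=rec.shed_externally,
            )
        )
    return results


def fold_range(results: Sequence[FluxResult]) -> float:
    """Spread of capture ratios: max ratio median / min ratio median."""
    medians = [r.ratio.median for r in results if r.ratio is not None]
    if not medians:
        raise ValueError("fold_range requires at least one result with a ratio")
    return max(medians) / min(medians)


def max_capture_fraction(results: Sequence[FluxResult]) -> LognormalQuantity:
    """The largest capture ratio — an upper bound on plasma capture efficiency."""
    with_ratio = [r for r in results if r.ratio is not None]
    if not with_ratio:
        raise ValueError("max_capture_fraction requires at least one ratio")
    return max(with_ratio, key=lambda r: r.ratio.median).ratio


def results_to_dataframe(results: Sequence[FluxResult]) -> pd.DataFrame:
    """Flatten results to the documented tabular schema."""
    rows = []
    for r in results:
        lo, hi = ci95(r.potential)
        rows.append(
            {
                "name": r.name,
                "potential_median": r.potential.median,
                "potential_lo": lo,
                "potential_hi": hi,
                "measured_median": r.measured.median if r.measured else np.nan,
                "ratio_median": r.ratio.median if r.ratio else np.nan,
                "ratio_lo": r.ci95_ratio[0] if r.ci95_ratio else np.nan,
                "ratio_hi": r.ci95_ratio[1] if r.ci95_ratio else np.nan,
                "detection": r.detection.value,
                "shed_externally": r.shed_externally,
            }
        )
    return pd.DataFrame(rows)


def write_results(results: Sequence[FluxResult], prefix: str | Path) -> tuple[Path, Path]:
    """Write results as ``<prefix>.csv`` and ``<prefix>.json``; returns paths."""
    prefix = Path(prefix)
    df = results_to_dataframe(results)
    csv_path = prefix.with_suffix(".csv")
    json_path = prefix.with_suffix(".json")
    df.to_csv(csv_path, index=False)
    payload = df.replace({np.nan: None}).to_dict(orient="records")
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return csv_path, json_path
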