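"""Packaged reference inputs.

``celltypes_synthetic.csv`` is a synthetic reconstruction of a healthy-adult
cell-type table: turnover rates at the order of magnitude of published
whole-body turnover estimates (erythrocyte progenitors ~2e11 cells/day down
to pancreatic beta cells ~3e4 cells/day), plasma cfDNA fractions in the
proportions reported by methylome deconvolution of healthy plasma
(granulocytes, megakaryocytes, lymphocytes, monocytes/macrophages,
erythroblasts, endothelium, hepatocytes), and multiplicative error factors
reflecting typical spread between source estimates.  It is not a copy of any
published supplementary file; individual entries are rounded, synthetic
stand-ins chosen to reproduce the published headline summaries (maximum
capture ratio, ratio extremes, fold-range) when run through this package.

Externally shed epithelia (gut, lung, kidney, bladder, skin) carry no
deconvolution fraction: their dying cells leave the body and contribute no
plasma cfDNA.
"""

from __future__ import annotations

from importlib.resources import as_file, files
from pathlib import Path

from .turnover import CellTypeRecord, load_celltype_table

__all__ = ["reference_table_path", "load_reference_table"]


def reference_table_path() -> Path:
    """Filesystem path of the packaged synthetic cell-type table."""
    resource = files("cfflux") / "data" / "celltypes_synthetic.csv"
    with as_file(resource) as p:
        return Path(p)


def load_reference_table() -> list[CellTypeRecord]:
    """Load the packaged synthetic cell-type table."""
    return load_celltype_table(reference_table_path())
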