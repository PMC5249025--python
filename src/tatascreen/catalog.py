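"""Packaged catalog of TATA-proximal SNP markers with published calls.

The catalog transcribes, row for row, the printed sequence contexts of known
and candidate SNP markers in TBP-binding regions of human gene promoters,
together with the published per-row outcome (K_D of both alleles in nM, the
integer Z, the significance bin, and the expression-change arrow).  The first
six columns form a regular SNP-context table; the ``*_expected`` columns are
the published values used for concordance checks and for calibrating the
default affinity model.
"""

from __future__ import annotations

import io
from importlib import resources

import pandas as pd

from .variants import SnpContext, parse_snp_table


def _raw_text() -> str:
    return resources.files("tatascreen.data").joinpath("known_markers.tsv").read_text()


def load_known_markers() -> list[SnpContext]:
    """The catalog as a parsed SNP-context table (expected columns ignored)."""
    return parse_snp_table(_raw_text())


def load_known_markers_frame() -> pd.DataFrame:
    """The full catalog, one row per rsid, including published expected values."""
    df = pd.read_csv(io.StringIO(_raw_text()), sep="\t", dtype=str)
    for col in ("kd_wt_expected", "kd_mut_expected", "z_expected"):
        df[col] = df[col].astype(float)
    return df
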