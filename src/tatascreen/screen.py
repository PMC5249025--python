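"""Batch screening of promoter SNPs for TBP-affinity changes.

``run_screen`` turns a parsed SNP-context table into one
:class:`MarkerRecord` per (rsid, minor allele): both allelic sequences are
scored with the affinity model, compared with the Fisher Z statistic, and the
predicted expression change is called.  Multi-allelic rows additionally mark
the first listed allele as the row-level summary: published catalogs print a
single K_D/Z per row and that value tracks the first listed minor allele, not
the strongest one (alleles of the same rsid can differ wildly — a C>T two
bases upstream of an ATAAAA element creates a perfect TATA box while C>A
barely perturbs it — so a max-effect summary would misrepresent such rows).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from . import compare as _cmp
from .affinity import AffinityModelConfig, estimate_affinity
from .compare import compare_estimates
from .variants import SnpContext, apply_alleles

log = logging.getLogger("tatascreen.screen")

_ALPHA_LABELS = {1e-6: "1e-06", 1e-3: "1e-03", 1e-2: "1e-02", 0.05: "0.05", None: "-"}
_ALPHA_FROM_LABEL = {v: k for k, v in _ALPHA_LABELS.items()}

_TSV_COLUMNS = [
    "rsid", "note", "wt", "mut",
    "kd_wt_nM", "kd_mut_nM", "kd_wt_display", "kd_mut_display",
    "z", "z_display", "p_value", "alpha", "direction",
    "wt_best_window_start", "mut_best_window_start", "row_summary",
]


def format_kd(x: float) -> str:
    """Display rounding for K_D in nM: two significant figures, no trailing .0."""
    if not math.isfinite(x) or x <= 0:
        return str(x)
    r = round(x, 1 - int(math.floor(math.log10(abs(x)))))
    return str(int(r)) if r == int(r) else str(r)


def format_z(z: float) -> str:
    """Display rounding for Z: nearest integer (catalogs print integer Z)."""
    return "inf" if math.isinf(z) else str(int(round(z)))


def format_alpha(alpha_bin: float | None) -> str:
    return _ALPHA_LABELS[alpha_bin]


@dataclass(frozen=True)
class MarkerRecord:
    """One screened (rsid, minor allele) pair with its comparison outcome."""

    rsid: str
    note: str
    wt_allele: str
    mut_allele: str
    wt_kd_nM: float
    mut_kd_nM: float
    z: float
    p_value: float
    alpha_bin: float | None
    direction: str
    wt_best_window_start: int
    mut_best_window_start: int
    row_summary: bool  # True for the first listed allele of its rsid


@dataclass(frozen=True)
class RowFailure:
    rsid: str
    error: str


@dataclass
class ScreenResult:
    records: list[MarkerRecord]
    failures: list[RowFailure]

    @property
    def ok(self) -> bool:
        return not self.failures

    def summaries(self) -> list[MarkerRecord]:
        """Row-level summary records only (one per rsid)."""
        return [r for r in self.records if r.row_summary]


def screen_context(ctx: SnpContext, cfg: AffinityModelConfig) -> list[MarkerRecord]:
    """Score and compare every minor allele of one SNP context."""
    wt_seq, mut_seqs = apply_alleles(ctx)
    wt_est = estimate_affinity(wt_seq, cfg)
    records = []
    for allele, mut_seq in zip(ctx.mut_alleles, mut_seqs):
        res = compare_estimates(wt_est, estimate_affinity(mut_seq, cfg))
        records.append(
            MarkerRecord(
                rsid=ctx.rsid,
                note=ctx.note,
                wt_allele=ctx.wt,
                mut_allele=allele,
                wt_kd_nM=res.wt.kd_nM,
                mut_kd_nM=res.mut.kd_nM,
                z=res.z,
                p_value=res.p_value,
                alpha_bin=res.alpha_bin,
                direction=res.direction,
                wt_best_window_start=res.wt.best_window_start,
                mut_best_window_start=res.mut.best_window_start,
                row_summary=False,
            )
        )
    records[0] = replace(records[0], row_summary=True)
    return records


def run_screen(snp_table: Iterable[SnpContext], cfg: AffinityModelConfig) -> ScreenResult:
    """Screen a whole SNP-context table; row failures never abort the batch."""
    records: list[MarkerRecord] = []
    failures: list[RowFailure] = []
    for ctx in snp_table:
        try:
            recs = screen_context(ctx, cfg)
        except Exception as e:  # row-level containment
            failures.append(RowFailure(rsid=ctx.rsid, error=str(e)))
            log.warning("row %s failed: %s", ctx.rsid, e)
            continue
        for r in recs:
            log.info(
                "%s %s>%s best_window=%d z=%.2f %s",
                r.rsid, r.wt_allele, r.mut_allele, r.mut_best_window_start, r.z, r.direction,
            )
        records.extend(recs)
    return ScreenResult(records=records, failures=failures)


def _record_to_row(r: MarkerRecord) -> list[str]:
    return [
        r.rsid, r.note, r.wt_allele, r.mut_allele,
        repr(r.wt_kd_nM), repr(r.mut_kd_nM), format_kd(r.wt_kd_nM), format_kd(r.mut_kd_nM),
        repr(r.z), format_z(r.z), repr(r.p_value), format_alpha(r.alpha_bin), r.direction,
        str(r.wt_best_window_start), str(r.mut_best_window_start), str(int(r.row_summary)),
    ]


def write_report(records: Sequence[MarkerRecord], format: str = "tsv") -> str:
    """Render records as lossless TSV or a human-readable markdown table.

    The TSV carries full-precision values (``repr``) alongside the display
    columns, so :func:`read_report` round-trips it exactly.
    """
    if format == "tsv":
        lines = ["\t".join(_TSV_COLUMNS)]
        lines += ["\t".join(_record_to_row(r)) for r in records]
        return "\n".join(lines) + "\n"
    if format == "markdown":
        arrows = {_cmp.UP: "↑", _cmp.DOWN: "↓", _cmp.INSIGNIFICANT: "="}
        header = ["rsid", "gene", "wt/mut", "K_D wt, nM", "K_D mut, nM", "Δ", "Z", "α"]
        lines = ["| " + " | ".join(header) + " |", "|" + "---|" * len(header)]
        for r in records:
            lines.append(
                "| "
                + " | ".join(
                    [
                        r.rsid, r.note, f"{r.wt_allele}/{r.mut_allele}",
                        format_kd(r.wt_kd_nM), format_kd(r.mut_kd_nM),
                        arrows[r.direction], format_z(r.z), format_alpha(r.alpha_bin),
                    ]
                )
                + " |"
            )
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown report format {format!r}")


def read_report(text: str) -> list[MarkerRecord]:
    """Parse a TSV report written by :func:`write_report` back into records."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or lines[0].split("\t") != _TSV_COLUMNS:
        raise ValueError("not a tatascreen TSV report")
    records = []
    for ln in lines[1:]:
        f = dict(zip(_TSV_COLUMNS, ln.split("\t")))
        records.append(
            MarkerRecord(
                rsid=f["rsid"], note=f["note"], wt_allele=f["wt"], mut_allele=f["mut"],
                wt_kd_nM=float(f["kd_wt_nM"]), mut_kd_nM=float(f["kd_mut_nM"]),
                z=float(f["z"]), p_value=float(f["p_value"]),
                alpha_bin=_ALPHA_FROM_LABEL[f["alpha"]], direction=f["direction"],
                wt_best_window_start=int(f["wt_best_window_start"]),
                mut_best_window_start=int(f["mut_best_window_start"]),
                row_summary=bool(int(f["row_summary"])),
            )
        )
    return records
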