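"""SNP contexts, promoter sequences, and allele application.

A SNP is described the way candidate-marker catalogs print it: a 5' flank,
the ancestral (wt) allele, one or more minor (mut) alleles, and a 3' flank,
all on the sense strand relative to the transcription start site (TSS).
Applying an allele is plain concatenation, so insertion/deletion alleles
produce variant sequences of different length.

Coordinates are TSS-relative, 1-based and negative upstream; the canonical
proximal-promoter analysis region is [-70; -20], a 51-nt window that contains
the known TATA-type TBP-binding sites of human protein-coding genes.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, TextIO

from Bio import SeqIO

DELETION_TOKEN = "-"

#: Inclusive TSS-relative bounds of the canonical analysis region.
REGION_START, REGION_END = -70, -20
REGION_LENGTH = REGION_END - REGION_START + 1  # 51 nt

_VALID_SEQ = re.compile(r"^[ACGT]+$")

_TSV_COLUMNS = ["rsid", "flank5", "wt", "mut", "flank3", "note"]


class SnpTableError(ValueError):
    """Malformed SNP-context table input (carries the offending line number)."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


def _normalize(seq: str, what: str, *, allow_deletion: bool = False, line: int | None = None) -> str:
    s = seq.strip().upper()
    if allow_deletion and s == DELETION_TOKEN:
        return s
    if not s:
        raise SnpTableError(f"field '{what}' is empty", line)
    if not _VALID_SEQ.match(s):
        raise SnpTableError(f"field '{what}' contains non-ACGT characters: {seq!r}", line)
    return s


@dataclass(frozen=True)
class SnpContext:
    """One catalog row: a SNP with its printed sequence context.

    ``wt`` is the ancestral allele (never the deletion token); each element of
    ``mut_alleles`` is a minor allele, where ``"-"`` denotes a deletion.
    """

    rsid: str
    flank5: str
    wt: str
    mut_alleles: tuple[str, ...]
    flank3: str
    note: str = ""

    def __post_init__(self):
        object.__setattr__(self, "flank5", _normalize(self.flank5, "flank5"))
        object.__setattr__(self, "flank3", _normalize(self.flank3, "flank3"))
        object.__setattr__(self, "wt", _normalize(self.wt, "wt"))
        muts = tuple(_normalize(a, "mut", allow_deletion=True) for a in self.mut_alleles)
        if not muts:
            raise SnpTableError(f"{self.rsid}: no minor alleles given")
        if any(a == self.wt for a in muts):
            raise SnpTableError(f"{self.rsid}: a minor allele equals the ancestral allele")
        object.__setattr__(self, "mut_alleles", muts)


@dataclass(frozen=True)
class PromoterSequence:
    """A promoter nucleotide string with optional TSS-relative anchoring.

    ``tss_offset_of_first_base`` is the 1-based negative TSS-relative
    coordinate of the first base (e.g. -70 for the canonical region); ``None``
    for bare catalog contexts whose genomic anchor is not printed.
    """

    seq: str
    origin: str = "table_context"  # table_context | fasta | synthetic
    tss_offset_of_first_base: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "seq", _normalize(self.seq, "seq"))
        if self.origin not in ("table_context", "fasta", "synthetic"):
            raise ValueError(f"unknown origin {self.origin!r}")

    def __len__(self) -> int:
        return len(self.seq)


def parse_snp_table(stream: TextIO | str) -> list[SnpContext]:
    """Parse a tab-separated SNP-context table into :class:`SnpContext` rows.

    Expected header columns: ``rsid  flank5  wt  mut  flank3  note`` (note is
    optional). The ``mut`` column may hold several comma-separated alleles;
    order is preserved. Raises :class:`SnpTableError` with the line number on
    malformed rows.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    lines = stream.read().splitlines()
    if not lines:
        raise SnpTableError("empty input: missing header")
    header = [h.strip().lower() for h in lines[0].split("\t")]
    missing = [c for c in _TSV_COLUMNS[:5] if c not in header]
    if missing:
        raise SnpTableError(f"header missing columns: {', '.join(missing)}", line=1)
    idx = {c: header.index(c) for c in _TSV_COLUMNS if c in header}

    rows: list[SnpContext] = []
    for ln, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        parts = raw.split("\t")
        required_width = max(idx[c] for c in _TSV_COLUMNS[:5]) + 1
        if len(parts) < required_width:
            raise SnpTableError(f"expected at least {required_width} fields, got {len(parts)}", line=ln)
        try:
            get = lambda c: parts[idx[c]].strip() if idx.get(c, len(parts)) < len(parts) else ""
            mut_alleles = tuple(a.strip() for a in get("mut").split(",") if a.strip())
            rows.append(
                SnpContext(
                    rsid=get("rsid"),
                    flank5=get("flank5"),
                    wt=get("wt"),
                    mut_alleles=mut_alleles,
                    flank3=get("flank3"),
                    note=get("note"),
                )
            )
        except SnpTableError as e:
            raise SnpTableError(str(e), line=ln) from None
    return rows


def write_snp_table(rows: Iterable[SnpContext]) -> str:
    """Serialize rows back to the TSV layout accepted by :func:`parse_snp_table`."""
    out = ["\t".join(_TSV_COLUMNS)]
    for r in rows:
        out.append(
            "\t".join([r.rsid, r.flank5, r.wt, ",".join(r.mut_alleles), r.flank3, r.note])
        )
    return "\n".join(out) + "\n"


def apply_alleles(ctx: SnpContext) -> tuple[PromoterSequence, list[PromoterSequence]]:
    """Build the ancestral and each minor variant sequence from a context row.

    The deletion token contributes zero characters, so indel variants differ
    in length from the ancestral sequence:
    ``len(mut) - len(wt) = len(allele_effective) - len(wt_allele)``.
    """
    wt_seq = PromoterSequence(ctx.flank5 + ctx.wt + ctx.flank3, origin="table_context")
    muts = []
    for allele in ctx.mut_alleles:
        eff = "" if allele == DELETION_TOKEN else allele
        muts.append(PromoterSequence(ctx.flank5 + eff + ctx.flank3, origin="table_context"))
    return wt_seq, muts


def read_promoter_fasta(handle: TextIO | str) -> list[PromoterSequence]:
    """Read promoters from FASTA.

    The description line may carry ``gene|tss_offset`` after the identifier;
    when the last ``|``-separated token parses as an integer it is taken as
    the TSS-relative coordinate of the first base.
    """
    if isinstance(handle, str):
        handle = io.StringIO(handle)
    promoters = []
    for rec in SeqIO.parse(handle, "fasta"):
        offset = None
        tokens = rec.description.split("|")
        if len(tokens) > 1:
            try:
                offset = int(tokens[-1].strip())
            except ValueError:
                offset = None
        promoters.append(
            PromoterSequence(str(rec.seq), origin="fasta", tss_offset_of_first_base=offset)
        )
    return promoters
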