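"""Synthetic TATA-proximal promoters and SNP events with known ground truth.

The generator emulates the input the screening pipeline sees in real use:
51-nt proximal-promoter regions ([-70; -20] relative to the TSS) carrying
exactly one planted TATA-class box, and one SNP event per promoter drawn
from the mutational types seen in marker catalogs (single-base substitution,
1–2-nt deletion, multi-allelic substitution).  Each event has an intended
qualitative effect:

* ``consensus_breaking`` — alters a box position currently at the model's
  maximal-weight base (expected affinity loss, direction "down");
* ``consensus_improving`` — moves a deliberately weakened box position to the
  maximal-weight base (expected affinity gain, direction "up");
* ``neutral_flank`` — hits the flank at least half a window away from the box
  centre (expected no significant change).

What it does not emulate: multi-box promoters, strand ambiguity, and the
correlated base composition of real human promoters; sequences are i.i.d.
with a fixed GC background outside the planted box.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .affinity import AffinityModelConfig, BASES
from .variants import DELETION_TOKEN, PromoterSequence, SnpContext

SNP_TYPES = ("substitution", "deletion_1nt", "deletion_2nt", "multiallelic")
EFFECTS = ("consensus_breaking", "consensus_improving", "neutral_flank")


class SimSpecError(ValueError):
    """Infeasible or inconsistent simulation specification."""


@dataclass(frozen=True)
class SimSpec:
    """Study conditions for one simulation run; the seed fully determines output."""

    seed: int
    n_promoters: int = 100
    region_length: int = 51
    gc_background: float = 0.6
    tata_motif: str | None = None  # None: plant the model's consensus motif
    tata_center_offset: int = -30  # TSS-relative centre of the planted box
    center_jitter: int = 3
    snp_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "substitution": 0.75, "deletion_1nt": 0.10, "deletion_2nt": 0.05, "multiallelic": 0.10,
        }
    )
    effect_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "consensus_breaking": 0.5, "consensus_improving": 0.2, "neutral_flank": 0.3,
        }
    )


@dataclass
class SimResult:
    promoters: list[tuple[str, PromoterSequence]]
    snp_contexts: list[SnpContext]
    truth: pd.DataFrame

    def promoters_fasta(self) -> str:
        out = []
        for name, p in self.promoters:
            out.append(f">{name}|{p.tss_offset_of_first_base}")
            out.append(p.seq)
        return "\n".join(out) + "\n"


def _validate(spec: SimSpec, cfg: AffinityModelConfig, motif: str) -> None:
    for name, mix, keys in (("snp_mix", spec.snp_mix, SNP_TYPES), ("effect_mix", spec.effect_mix, EFFECTS)):
        if set(mix) - set(keys):
            raise SimSpecError(f"{name} has unknown keys: {set(mix) - set(keys)}")
        if any(v < 0 for v in mix.values()) or abs(sum(mix.values()) - 1.0) > 1e-9:
            raise SimSpecError(f"{name} proportions must be non-negative and sum to 1")
    if spec.n_promoters < 1:
        raise SimSpecError("n_promoters must be >= 1")
    if not 0.0 < spec.gc_background < 1.0:
        raise SimSpecError("gc_background must be in (0, 1)")
    if spec.region_length < cfg.window_length:
        raise SimSpecError(
            f"region_length {spec.region_length} < model window {cfg.window_length}"
        )
    lo, hi = _center_index_range(spec)
    half = len(motif) // 2
    if lo - half < 0 or hi - half + len(motif) > spec.region_length:
        raise SimSpecError("region too short for the planted box at the requested offset/jitter")
    if spec.effect_mix.get("neutral_flank", 0) > 0:
        if not _neutral_positions(spec, cfg, lo, half, len(motif)):
            raise SimSpecError("no flank position is far enough from the box for neutral SNPs")


def _center_index_range(spec: SimSpec) -> tuple[int, int]:
    center = spec.tata_center_offset + 70  # region index of TSS offset -70 is 0
    return center - spec.center_jitter, center + spec.center_jitter


def _neutral_positions(spec, cfg, center_lo, half, motif_len) -> list[int]:
    # far enough from any jittered box centre, and never inside a box
    min_dist = (cfg.window_length + 1) // 2
    lo, hi = _center_index_range(spec)
    positions = []
    for pos in range(1, spec.region_length - 3):  # keep both flanks non-empty
        if lo - half <= pos < hi - half + motif_len:
            continue
        if min(abs(pos - c) for c in range(lo, hi + 1)) >= min_dist:
            positions.append(pos)
    return positions


def simulate(spec: SimSpec, cfg: AffinityModelConfig) -> SimResult:
    """Generate promoters, one SNP event each, and a ground-truth table.

    Returns FASTA-able promoters, an SNP-context table (full-region flanks)
    and a truth table labelling each event with its intended effect class.
    Two independent named random streams (sequences; SNP placement) are
    derived from the master seed, so enabling more SNP types never perturbs
    the sequences themselves.
    """
    motif = spec.tata_motif.upper() if spec.tata_motif else cfg.pwm_argmax()
    _validate(spec, cfg, motif)
    rng_seq = np.random.default_rng([spec.seed, 0])
    rng_snp = np.random.default_rng([spec.seed, 1])

    consensus = cfg.pwm_argmax()
    argmin = cfg.pwm_argmin()
    # discriminative box positions (weight span in the top half) for events
    spans = [row[consensus[i]] - row[argmin[i]] for i, row in enumerate(cfg.pwm)]
    cutoff = float(np.median(spans))
    strong = [i for i, s in enumerate(spans) if s >= cutoff and s > 0]
    if not strong:
        raise SimSpecError("model PWM has no discriminative positions to mutate")

    gc, at = spec.gc_background / 2.0, (1.0 - spec.gc_background) / 2.0
    base_p = np.array([at, gc, gc, at])  # A C G T
    lo, hi = _center_index_range(spec)
    half = len(motif) // 2

    promoters, contexts, truth_rows = [], [], []
    for k in range(spec.n_promoters):
        bg = "".join(np.array(list(BASES))[rng_seq.choice(4, size=spec.region_length, p=base_p)])
        center = int(rng_seq.integers(lo, hi + 1))
        box_start = center - half

        effect = str(rng_snp.choice(EFFECTS, p=[spec.effect_mix.get(e, 0.0) for e in EFFECTS]))
        snp_type = str(rng_snp.choice(SNP_TYPES, p=[spec.snp_mix.get(t, 0.0) for t in SNP_TYPES]))
        # improving events need a restorable substitution; multi-allelic sets
        # cannot all improve toward the single best base
        if effect == "consensus_improving" and snp_type in ("deletion_1nt", "deletion_2nt", "multiallelic"):
            snp_type = "substitution"

        planted = motif
        if effect == "consensus_improving":
            usable = [i for i in strong if 1 <= box_start + i <= spec.region_length - 2]
            if not usable:
                raise SimSpecError("no discriminative box position with both flanks non-empty")
            i = int(rng_snp.choice(usable))
            weak = argmin[i] if argmin[i] != planted[i] else min(
                (b for b in BASES if b != consensus[i]), key=lambda b: cfg.pwm[i][b]
            )
            planted = planted[:i] + weak + planted[i + 1 :]
            pos, wt_allele, alleles = box_start + i, weak, [consensus[i]]
        elif effect == "consensus_breaking":
            wt_len_here = 2 if snp_type == "deletion_2nt" else 1
            candidates = [
                i for i in strong
                if planted[i] == consensus[i]
                and 1 <= box_start + i <= spec.region_length - 1 - wt_len_here
            ]
            if not candidates:
                raise SimSpecError("planted motif has no consensus base at a usable discriminative position")
            i = int(rng_snp.choice(candidates))
            pos = box_start + i
            if snp_type == "deletion_1nt":
                wt_allele, alleles = planted[i], [DELETION_TOKEN]
            elif snp_type == "deletion_2nt":
                wt_allele, alleles = None, [DELETION_TOKEN]  # filled after assembly
            else:
                others = [b for b in BASES if b != planted[i]]
                n_alt = int(rng_snp.integers(2, 4)) if snp_type == "multiallelic" else 1
                alleles = list(rng_snp.choice(others, size=n_alt, replace=False))
                wt_allele = planted[i]
        else:  # neutral_flank
            positions = _neutral_positions(spec, cfg, lo, half, len(motif))
            pos = int(rng_snp.choice(positions))
            wt_allele = None
            if snp_type in ("deletion_1nt", "deletion_2nt"):
                alleles = [DELETION_TOKEN]
            else:
                alleles = None  # resolved against the assembled sequence below

        seq = bg[:box_start] + planted + bg[box_start + len(planted) :]
        wt_len = 2 if snp_type == "deletion_2nt" else 1
        if wt_allele is None or snp_type == "deletion_2nt":
            wt_allele = seq[pos : pos + wt_len]
        if alleles is None:  # neutral substitution/multiallelic drawn vs the real base
            others = [b for b in BASES if b != seq[pos]]
            n_alt = int(rng_snp.integers(2, 4)) if snp_type == "multiallelic" else 1
            alleles = list(rng_snp.choice(others, size=n_alt, replace=False))

        name = f"sim{k:04d}"
        promoters.append(
            (name, PromoterSequence(seq, origin="synthetic", tss_offset_of_first_base=-70))
        )
        contexts.append(
            SnpContext(
                rsid=f"{name}_snp",
                flank5=seq[:pos],
                wt=wt_allele,
                mut_alleles=tuple(alleles),
                flank3=seq[pos + wt_len :],
                note=name,
            )
        )
        truth_rows.append(
            {
                "promoter": name, "rsid": f"{name}_snp", "effect": effect,
                "snp_type": snp_type, "position": pos, "box_start": box_start,
            }
        )

    return SimResult(
        promoters=promoters,
        snp_contexts=contexts,
        truth=pd.DataFrame(truth_rows),
    )
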