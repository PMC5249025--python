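"""TBP–promoter affinity estimation.

The equilibrium dissociation constant of the TBP–DNA complex is modelled on
the -ln(K_D) scale (K_D in mol/L, sign-flipped so that larger values mean
tighter binding).  A fixed-length window is scored as a linear combination of
three mechanism terms reflecting the stepwise formation of the complex:

* a *sliding* term — nonspecific one-dimensional diffusion of TBP along the
  double helix, captured by the mean of a dinucleotide stacking-energy scale
  over the window;
* a *recognition* term — specific readout of a TATA-like element, the maximal
  positional-weight-matrix (PWM) score over all motif placements inside the
  window;
* a *bending* term — the DNA helix deformation that accompanies minor-groove
  binding, captured by the mean of a TA/TV dinucleotide flexibility scale.

The affinity of a promoter is the maximum of the window score over all
windows, reported together with a standard deviation ``delta`` that feeds the
Z comparison of allelic variants.  All model parameters live in a plain-text
(YAML) config; the packaged default was calibrated against published
K_D measurements for TATA-proximal promoter variants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import yaml

BASES = "ACGT"
DINUCLEOTIDES = tuple(a + b for a in BASES for b in BASES)

#: Below this length a sequence cannot be scored at all.
MIN_SCORABLE_LENGTH = 10


class ModelConfigError(ValueError):
    """Schema violation in an affinity-model config."""


@dataclass(frozen=True)
class AffinityModelConfig:
    """Parameter set of the three-term affinity model.

    ``linear_coeffs`` maps ``intercept``, ``sliding``, ``recognition`` and
    ``bending`` to the coefficients combining the mechanism terms; ``pwm`` is a
    per-position, per-base weight table for the TATA-like motif;
    ``slide_weights`` and ``bend_weights`` are complete 16-entry dinucleotide
    tables.  ``delta_method`` selects how the standard deviation of the
    estimate is computed: ``constant`` (the calibrated model uncertainty
    ``delta_constant``) or ``window_sd`` (dispersion of the best window score
    under single-base perturbation, for sensitivity analysis).
    """

    window_length: int
    pwm: tuple[Mapping[str, float], ...]
    slide_weights: Mapping[str, float]
    bend_weights: Mapping[str, float]
    linear_coeffs: Mapping[str, float]
    delta_method: str = "constant"
    delta_constant: float = 0.0

    def __post_init__(self):
        if self.window_length < MIN_SCORABLE_LENGTH:
            raise ModelConfigError(f"window_length must be >= {MIN_SCORABLE_LENGTH}")
        if self.delta_method not in ("constant", "window_sd"):
            raise ModelConfigError(f"unknown delta_method {self.delta_method!r}")
        if self.delta_constant < 0:
            raise ModelConfigError("delta_constant must be >= 0")
        for name, table in (("slide_weights", self.slide_weights), ("bend_weights", self.bend_weights)):
            missing = [d for d in DINUCLEOTIDES if d not in table]
            if missing:
                raise ModelConfigError(f"{name} missing entries: {', '.join(missing)}")
        if not self.pwm:
            raise ModelConfigError("pwm must have at least one position")
        for i, row in enumerate(self.pwm):
            missing = [b for b in BASES if b not in row]
            if missing:
                raise ModelConfigError(f"pwm position {i} missing bases: {', '.join(missing)}")
        expected = {"intercept", "sliding", "recognition", "bending"}
        if set(self.linear_coeffs) != expected:
            raise ModelConfigError(
                f"linear_coeffs must have exactly the keys {sorted(expected)}"
            )

    @property
    def motif_length(self) -> int:
        return len(self.pwm)

    def pwm_neutral(self) -> tuple[float, ...]:
        """Per-position neutral value: the mean weight over the four bases."""
        return tuple(sum(row[b] for b in BASES) / 4.0 for row in self.pwm)

    def pwm_argmax(self) -> str:
        """The maximal-weight base at each motif position (consensus)."""
        return "".join(max(BASES, key=lambda b: row[b]) for row in self.pwm)

    def pwm_argmin(self) -> str:
        """The minimal-weight base at each motif position."""
        return "".join(min(BASES, key=lambda b: row[b]) for row in self.pwm)


@dataclass(frozen=True)
class AffinityEstimate:
    """Maximal -ln(K_D) over windows with its standard deviation.

    ``kd_nM`` is the derived dissociation constant in nmol/L;
    ``best_window_start`` is the 0-based offset of the (leftmost) maximal
    window in the input sequence.
    """

    neg_ln_kd: float
    delta: float
    kd_nM: float
    best_window_start: int
    per_window_scores: tuple[float, ...]


def kd_nanomolar(neg_ln_kd: float) -> float:
    """Convert -ln(K_D in mol/L) to a dissociation constant in nmol/L."""
    return math.exp(-neg_ln_kd) * 1e9


def _dinuc_mean(seq: str, table: Mapping[str, float]) -> float:
    if len(seq) < 2:
        return 0.0
    return sum(table[seq[i : i + 2]] for i in range(len(seq) - 1)) / (len(seq) - 1)


def _recognition(seq: str, cfg: AffinityModelConfig) -> float:
    """Max motif-placement score; placements run past the end with neutral fill.

    For sequences shorter than the motif the single left-anchored placement is
    used and every missing position contributes its per-position neutral value
    (the mean weight over bases), so truncated catalog contexts remain
    scorable.
    """
    m = cfg.motif_length
    pwm = cfg.pwm
    neutral = cfg.pwm_neutral()
    n_placements = max(1, len(seq) - m + 1)
    best = -math.inf
    for p in range(n_placements):
        s = 0.0
        for i in range(m):
            j = p + i
            s += pwm[i][seq[j]] if j < len(seq) else neutral[i]
        if s > best:
            best = s
    return best


def score_window(w: str, cfg: AffinityModelConfig) -> float:
    """Score one window on the -ln(K_D in mol/L) scale.

    ``w`` must be an upper-case A/C/G/T string of ``cfg.window_length``
    (shorter sequences are handled by :func:`estimate_affinity`, which owns
    the truncated-window convention).
    """
    if len(w) != cfg.window_length:
        raise ValueError(f"window must be {cfg.window_length} nt, got {len(w)}")
    return _score_any(w, cfg)


def _score_any(seq: str, cfg: AffinityModelConfig) -> float:
    c = cfg.linear_coeffs
    return (
        c["intercept"]
        + c["sliding"] * _dinuc_mean(seq, cfg.slide_weights)
        + c["recognition"] * _recognition(seq, cfg)
        + c["bending"] * _dinuc_mean(seq, cfg.bend_weights)
    )


def _window_sd(best_window: str, cfg: AffinityModelConfig) -> float:
    """SD of the best window's score over all single-base substitutions."""
    scores = []
    for i, b0 in enumerate(best_window):
        for b in BASES:
            if b == b0:
                continue
            scores.append(_score_any(best_window[:i] + b + best_window[i + 1 :], cfg))
    mean = sum(scores) / len(scores)
    return math.sqrt(sum((s - mean) ** 2 for s in scores) / len(scores))


def estimate_affinity(p, cfg: AffinityModelConfig) -> AffinityEstimate:
    """Estimate the TBP affinity of a promoter sequence.

    The estimate is the maximum of :func:`score_window` over all contiguous
    windows of ``cfg.window_length``; ties are broken toward the smallest
    start offset.  A sequence shorter than the window (but at least
    ``MIN_SCORABLE_LENGTH`` nt, as for printed catalog contexts) is scored as
    a single truncated window: the dinucleotide terms average over the
    positions present and motif placements that overhang the end contribute
    per-position neutral values.
    """
    seq = p.seq if hasattr(p, "seq") else str(p)
    seq = seq.upper()
    if len(seq) < MIN_SCORABLE_LENGTH:
        raise ValueError(
            f"sequence of {len(seq)} nt is too short to score (< {MIN_SCORABLE_LENGTH})"
        )
    L = cfg.window_length
    if len(seq) <= L:
        windows = [seq]
    else:
        windows = [seq[i : i + L] for i in range(len(seq) - L + 1)]
    scores = tuple(_score_any(w, cfg) for w in windows)
    best_start = max(range(len(scores)), key=lambda i: (scores[i], -i))
    neg_ln_kd = scores[best_start]
    if cfg.delta_method == "constant":
        delta = cfg.delta_constant
    else:
        delta = _window_sd(windows[best_start], cfg)
    return AffinityEstimate(
        neg_ln_kd=neg_ln_kd,
        delta=delta,
        kd_nM=kd_nanomolar(neg_ln_kd),
        best_window_start=best_start,
        per_window_scores=scores,
    )


# -- config I/O --------------------------------------------------------------

def _to_plain(cfg: AffinityModelConfig) -> dict:
    return {
        "format_version": 1,
        "window_length": cfg.window_length,
        "delta_method": cfg.delta_method,
        "delta_constant": float(cfg.delta_constant),
        "linear_coeffs": {k: float(v) for k, v in cfg.linear_coeffs.items()},
        "pwm": [{b: float(row[b]) for b in BASES} for row in cfg.pwm],
        "slide_weights": {d: float(cfg.slide_weights[d]) for d in DINUCLEOTIDES},
        "bend_weights": {d: float(cfg.bend_weights[d]) for d in DINUCLEOTIDES},
    }


def _from_plain(doc: dict) -> AffinityModelConfig:
    try:
        return AffinityModelConfig(
            window_length=int(doc["window_length"]),
            pwm=tuple(dict(row) for row in doc["pwm"]),
            slide_weights=dict(doc["slide_weights"]),
            bend_weights=dict(doc["bend_weights"]),
            linear_coeffs=dict(doc["linear_coeffs"]),
            delta_method=doc.get("delta_method", "constant"),
            delta_constant=float(doc.get("delta_constant", 0.0)),
        )
    except KeyError as e:
        raise ModelConfigError(f"config missing key: {e.args[0]}") from None


def load_model(path: str | Path) -> AffinityModelConfig:
    """Load and validate an affinity-model config from a YAML file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ModelConfigError("config must be a mapping")
    return _from_plain(doc)


def write_model(cfg: AffinityModelConfig, path: str | Path) -> None:
    """Write a config so that :func:`load_model` round-trips it exactly."""
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(cfg), fh, sort_keys=True)


def default_model() -> AffinityModelConfig:
    """The packaged default model config."""
    ref = resources.files("tatascreen.data").joinpath("default_model.yaml")
    with resources.as_file(ref) as path:
        return load_model(path)
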