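"""Over-representation scoring of gapped factors under an i.i.d. background.

The expected frequency of a pair D = (y, z) is the product of the component
frequencies, F_e(D) = f(y) f(z), converted to an expected count over the
admissible placements.  Because extending a component within its suffix-tree
equivalence class leaves the observed count F_c unchanged while F_e can only
shrink, every score in the family below attains its class maximum at the
pair of class representatives — so only proper-locus pairs need to be
scored.

The z-score family (z1..z4) and the dyad significance score are
reconstructions: they are defined here so that each compares F_c with F_e,
is monotone non-increasing in F_e at fixed F_c, and therefore satisfies the
representative-maximum property.  The significance score follows the RSAT
dyad-analysis convention: Signif = -log10(N_p * P(D, >= F_c)) with a
binomial upper tail over the admissible positions and N_p the number of
candidate dyads (a Bonferroni-style multiplicity correction).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Optional

from scipy.stats import binom

from .index import SuffixIndex, TreeNode
from .sequences import SequenceSet

__all__ = [
    "BackgroundModel", "ScoreSet", "expected_freq", "zscores",
    "significance", "prune_to_representatives",
]

_LOG10_TINY = math.log10(5e-324)  # smallest subnormal double


@dataclass(frozen=True)
class BackgroundModel:
    """Monadic (single-symbol, i.i.d.) background model.

    ``probs`` maps each alphabet symbol to its probability;
    ``record_lengths`` gives the effective positions for converting
    per-position probabilities into expected counts.
    """

    probs: dict[str, float]
    record_lengths: tuple[int, ...]
    source: str = "input"

    def __post_init__(self):
        total = sum(self.probs.values())
        if any(p < 0 for p in self.probs.values()) or not math.isclose(
                total, 1.0, rel_tol=1e-9, abs_tol=1e-12):
            raise ValueError(f"probabilities must be >= 0 and sum to 1 "
                             f"(got sum {total})")

    @classmethod
    def from_sequences(cls, seqs: SequenceSet,
                       source: str = "input") -> "BackgroundModel":
        """Estimate symbol frequencies from a sequence set (the estimates
        reproduce the symbol histogram exactly)."""
        counts = {c: 0 for c in sorted(seqs.alphabet)}
        for _, s in seqs.records:
            for c in s:
                counts[c] += 1
        n = seqs.total_length
        return cls({c: k / n for c, k in counts.items()}, seqs.lengths,
                   source)

    @classmethod
    def from_probs(cls, probs: dict[str, float],
                   record_lengths: tuple[int, ...],
                   source: str = "external") -> "BackgroundModel":
        return cls(dict(probs), tuple(record_lengths), source)

    def word_prob(self, w: str) -> float:
        p = 1.0
        for c in w:
            p *= self.probs.get(c, 0.0)
        return p

    def admissible_positions(self, span: int) -> int:
        """Number of start positions for a pattern of total span ``span``."""
        return sum(max(0, L - span + 1) for L in self.record_lengths)


@dataclass
class ScoreSet:
    """Observed count, expected frequency and the full score family."""

    F_c: int
    F_e: float
    z1: float
    z2: float
    z3: float
    z4: float
    signif: float = math.nan
    N_p: int = 0
    P_tail: float = math.nan

    def get(self, name: str) -> float:
        try:
            return getattr(self, name)
        except AttributeError:
            raise KeyError(f"unknown score {name!r}") from None


def expected_freq(y: str, z: str, bg: BackgroundModel, gap: int = 0,
                  counted_freq: Optional[Callable[[str], float]] = None,
                  ) -> float:
    """Expected co-occurrence count F_e(D) = f(y) f(z) x admissible positions.

    ``f`` is the product of background symbol probabilities, or — in the
    counted-frequency setting used by the dyad pipeline — the observed
    per-position relative frequency of each component, supplied via
    ``counted_freq``.  ``gap`` is the tail-to-head spacer length of the
    placement (0 for abutting components).
    """
    if not y or not z:
        raise ValueError("components must be non-empty")
    if gap < 0:
        raise ValueError("gap must be >= 0")
    f = counted_freq if counted_freq is not None else bg.word_prob
    span = len(y) + gap + len(z)
    return f(y) * f(z) * bg.admissible_positions(span)


def zscores(F_c: float, F_e: float,
            n_positions: Optional[int] = None
            ) -> tuple[float, float, float, float]:
    """The four over-representation scores comparing F_c with F_e.

    z1 = F_c - F_e; z2 = F_c / F_e; z3 = (F_c - F_e) / sqrt(F_e);
    z4 = (F_c - F_e) / sqrt(F_e (1 - F_e / N)) with N the admissible
    position count.  Larger means more over-represented, and each score is
    monotone non-increasing in F_e at fixed F_c — including at F_e = 0,
    where a positive observation against a zero expectation scores +inf
    for z2..z4 (and a zero observation leaves them as NaN sentinels,
    z1 = F_c either way).
    """
    if F_c < 0 or F_e < 0:
        raise ValueError("F_c and F_e must be non-negative")
    z1 = F_c - F_e
    if F_e == 0:
        if F_c > 0:
            return z1, math.inf, math.inf, math.inf
        return z1, math.nan, math.nan, math.nan
    z2 = F_c / F_e
    z3 = (F_c - F_e) / math.sqrt(F_e)
    if n_positions is None or n_positions <= 0 or F_e >= n_positions:
        z4 = math.nan
    else:
        z4 = (F_c - F_e) / math.sqrt(F_e * (1.0 - F_e / n_positions))
    return z1, z2, z3, z4


def binomial_tail(F_c: int, rate: float, n_positions: int) -> float:
    """P(X >= F_c) for X ~ Binomial(n_positions, rate)."""
    if F_c <= 0:
        return 1.0
    return float(binom.sf(F_c - 1, n_positions, rate))


def significance(F_c: int, F_e_rate: float, N_p: int,
                 n_positions: int) -> float:
    """Dyad significance: -log10(N_p * P(D, >= F_c)).

    ``P(D, >= n)`` is the binomial probability of observing at least the
    counted number of dyad occurrences in ``n_positions`` trials with
    per-position success probability ``F_e_rate``; ``N_p`` is the number of
    unique candidate dyads of the run.  Larger = more over-represented;
    P * N_p = 1 gives 0.
    """
    if not (0.0 <= F_e_rate <= 1.0):
        raise ValueError("F_e_rate must lie in [0, 1]")
    if F_c > n_positions:
        raise ValueError("F_c cannot exceed the number of positions")
    if N_p < 1:
        raise ValueError("N_p must be >= 1")
    if F_c <= 0:
        log10_p = 0.0
    else:
        log_p = float(binom.logsf(F_c - 1, n_positions, F_e_rate))
        if math.isinf(log_p):
            warnings.warn("binomial tail underflow; clamping to the "
                          "smallest representable tail", RuntimeWarning,
                          stacklevel=2)
            log10_p = _LOG10_TINY
        else:
            log10_p = log_p / math.log(10)
    return -(math.log10(N_p) + log10_p)


def prune_to_representatives(index: SuffixIndex
                             ) -> list[tuple[TreeNode, TreeNode]]:
    """All proper-locus pairs (y_node, z_node): the class representatives.

    Any pair of words not emitted shares its counts with — and scores no
    higher than — the emitted pair of its class representatives.
    """
    reps = [n for n in index.nodes if n.has_word_class]
    return [(a, b) for a in reps for b in reps]
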