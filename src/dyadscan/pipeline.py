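"""Spaced-dyad discovery: enumerate, count, score and rank word pairs.

A spaced dyad is a gapped factor with short fixed-length components (the
classic case is the Gal4p zinc-cluster site CGG-N11-CCG: two conserved
trinucleotides separated by a fixed-length spacer of variable content).
The pipeline emulates dyad-analysis-style discovery: every pair of
length-k words present in the sequence set is counted at each tail-to-head
gap in [d_min, d_max] with the suffix-tree machinery, expected frequencies
come from the product of the counted component frequencies, and dyads are
ranked by the over-representation scores.

In both-strand mode the reverse complements of the records are added to
the scanned set, so the count of a dyad automatically pools the dyad with
its reverse complement; only one canonical member of each strand pair is
reported.
"""

from __future__ import annotations

import math
import sys
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, TextIO

from .counts import th_exact_query
from .index import SuffixIndex, build_index
from .scoring import BackgroundModel, ScoreSet, significance, zscores
from .sequences import SequenceSet, reverse_complement

__all__ = ["DyadRecord", "enumerate_dyads", "rank_dyads", "match_consensus",
           "write_dyads_tsv"]

SCORE_NAMES = ("z1", "z2", "z3", "z4", "signif")

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass
class DyadRecord:
    """One scored spaced dyad: (y, spacer, z) with counts and scores."""

    y: str
    gap: int | tuple[int, int]
    z: str
    strand_collapsed: bool
    F_c: int
    scores: Optional[ScoreSet] = None
    ranks: dict[str, int] = field(default_factory=dict)

    @property
    def pattern(self) -> str:
        g = self.gap if isinstance(self.gap, int) else self.gap[0]
        return self.y + "n" * g + self.z


def _canonical(y: str, gap, z: str) -> tuple[str, object, str]:
    """Lexicographically smaller of a dyad and its reverse complement."""
    rc = (reverse_complement(z), gap, reverse_complement(y))
    return min((y, gap, z), rc, key=lambda t: (t[0], t[2]))


def enumerate_dyads(
    seqs: SequenceSet,
    k: int = 3,
    d_min: int = 0,
    d_max: int = 16,
    strands: str = "both",
    per_gap: bool = True,
    score: bool = True,
    bg: Optional[BackgroundModel] = None,
) -> tuple[list[DyadRecord], int]:
    """Enumerate and score all spaced dyads of a sequence set.

    Returns ``(records, N_p)`` where records cover every unique
    (y, gap, z) — canonical strand representative in both-strand mode —
    with F_c > 0, and N_p is the number of unique candidate dyads under
    the run's settings (used inside the significance score).

    Candidates are the length-k words actually present in the scanned
    set (the suffix-tree leaves), not all |alphabet|^k possibilities;
    absent words contribute nothing and are not part of N_p either.
    With ``per_gap`` (default, matching the fixed-spacing dyad notion)
    one record is emitted per exact gap; otherwise counts are aggregated
    over [d_min, d_max].
    """
    if k < 1:
        raise ValueError("component length k must be >= 1")
    if not (0 <= d_min <= d_max):
        raise ValueError("need 0 <= d_min <= d_max")
    if strands not in ("both", "single"):
        raise ValueError("strands must be 'both' or 'single'")
    scan = seqs.with_reverse_complements() if strands == "both" else seqs
    if bg is None:
        bg = BackgroundModel.from_sequences(scan)
    if bg.admissible_positions(2 * k + d_min) == 0:
        warnings.warn("every record is shorter than the smallest dyad span; "
                      "no candidates", RuntimeWarning, stacklevel=2)
        return [], 0
    idx = build_index(scan)
    kmers = idx.words_of_length(k)
    words = sorted(kmers)
    n_comp_positions = bg.admissible_positions(k)
    comp_freq = {w: kmers[w].occurrence_count / n_comp_positions
                 for w in words}

    cache: dict = {}
    collapsed = strands == "both"
    seen: set[tuple] = set()
    raw: list[DyadRecord] = []
    gaps = range(d_min, d_max + 1)
    for y in words:
        for h in gaps:
            for z in words:
                key = _canonical(y, h, z) if collapsed else (y, h, z)
                if key in seen:
                    continue
                seen.add(key)
                cy, ch, cz = key
                fc = th_exact_query(idx, cy, cz, ch, _cache=cache)
                raw.append(DyadRecord(cy, ch, cz, collapsed, fc))
    if not per_gap:
        agg: dict[tuple[str, str], DyadRecord] = {}
        for r in raw:
            cur = agg.get((r.y, r.z))
            if cur is None:
                agg[(r.y, r.z)] = DyadRecord(
                    r.y, (d_min, d_max), r.z, collapsed, r.F_c)
            else:
                cur.F_c += r.F_c
        raw = list(agg.values())
    n_p = len(raw)
    records = [r for r in raw if r.F_c > 0]
    if score:
        for r in records:
            _score_record(r, comp_freq, bg, n_p, d_min, d_max, k)
    return records, n_p


def _score_record(r: DyadRecord, comp_freq: dict[str, float],
                  bg: BackgroundModel, n_p: int,
                  d_min: int, d_max: int, k: int) -> None:
    rate = comp_freq[r.y] * comp_freq[r.z]
    if isinstance(r.gap, int):
        n_pos = bg.admissible_positions(2 * k + r.gap)
    else:
        n_pos = sum(bg.admissible_positions(2 * k + h)
                    for h in range(d_min, d_max + 1))
    f_e = rate * n_pos
    z1, z2, z3, z4 = zscores(r.F_c, f_e, n_positions=n_pos)
    sig = significance(min(r.F_c, n_pos), rate, n_p, n_pos)
    r.scores = ScoreSet(r.F_c, f_e, z1, z2, z3, z4, signif=sig, N_p=n_p)


def rank_dyads(records: Sequence[DyadRecord],
               score_name: str) -> list[DyadRecord]:
    """Sort descending by one score and assign competition ranks.

    Tied scores share the minimal rank of their block (1, 2, 2, 4, ...);
    the order *within* a tied block is by (y, gap, z), so the output is
    deterministic and independent of input order.  NaN scores sort last.
    """
    if score_name not in SCORE_NAMES:
        raise KeyError(f"unknown score {score_name!r}; "
                       f"choose from {SCORE_NAMES}")

    def sval(r: DyadRecord) -> float:
        v = r.scores.get(score_name) if r.scores is not None else math.nan
        return -math.inf if math.isnan(v) else v

    ordered = sorted(records,
                     key=lambda r: (-sval(r), r.y, r.gap, r.z))
    rank = 0
    prev = None
    for i, r in enumerate(ordered):
        v = sval(r)
        if prev is None or v != prev:
            rank = i + 1
            prev = v
        r.ranks[score_name] = rank
    return ordered


def match_consensus(dyad: DyadRecord, pattern: str) -> bool:
    """True iff the dyad aligns to an IUPAC consensus on either strand.

    ``pattern`` is an IUPAC string with 'n' spacer positions (e.g.
    "CGGnnnnnnGGA"); the dyad matches when its total span equals the
    pattern length, y matches the left end and z the right end (spacer
    content is unconstrained — a solid dyad carries no information about
    it).  The reverse complement of the dyad is also tried.
    """
    pat = pattern.upper()
    for c in pat:
        if c not in _IUPAC:
            raise ValueError(f"malformed IUPAC pattern symbol {c!r}")
    gap = dyad.gap if isinstance(dyad.gap, int) else dyad.gap[0]
    candidates = [(dyad.y, dyad.z)]
    candidates.append((reverse_complement(dyad.z), reverse_complement(dyad.y)))
    for y, z in candidates:
        if len(y) + gap + len(z) != len(pat):
            continue
        left = all(c in _IUPAC[p] for c, p in zip(y, pat[: len(y)]))
        right = all(c in _IUPAC[p] for c, p in zip(z, pat[len(pat) - len(z):]))
        if left and right:
            return True
    return False


def write_dyads_tsv(records: Iterable[DyadRecord], out: TextIO = sys.stdout,
                    params: Optional[dict] = None, n_p: int = 0) -> None:
    """Write scored dyads as TSV with '#' header lines echoing the run
    parameters and N_p."""
    if params:
        for key in sorted(params):
            out.write(f"# {key}={params[key]}\n")
    out.write(f"# N_p={n_p}\n")
    cols = ["y", "gap", "z", "strand_rep", "F_c", "F_e",
            "z1", "z2", "z3", "z4", "signif",
            "rank_z2", "rank_z3", "rank_signif"]
    out.write("\t".join(cols) + "\n")
    for r in records:
        s = r.scores
        gap = r.gap if isinstance(r.gap, int) else f"{r.gap[0]}-{r.gap[1]}"
        row = [r.y, str(gap), r.z,
               "both" if r.strand_collapsed else "fwd", str(r.F_c)]
        if s is None:
            row += ["NA"] * 6
        else:
            row += [f"{s.F_e:.6g}", f"{s.z1:.6g}", f"{s.z2:.6g}",
                    f"{s.z3:.6g}", f"{s.z4:.6g}", f"{s.signif:.6g}"]
        row += [str(r.ranks.get(k, "NA"))
                for k in ("z2", "z3", "signif")]
        out.write("\t".join(row) + "\n")
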