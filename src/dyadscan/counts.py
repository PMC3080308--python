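"""Co-occurrence counting for gapped factors under five distance semantics.

A gapped factor ``(y, z, d)`` asks how often an occurrence of ``z`` follows
an occurrence of ``y`` within distance ``d`` in the same record.  Distances
(1-based start positions ``p`` for ``y``, ``q`` for ``z``):

``HH`` (head-to-head)
    ``1 <= q - p <= d``.
``TH`` (tail-to-head)
    gap between the end of ``y`` and the start of ``z``:
    ``0 <= q - (p + |y|) <= d``.
``HT`` (head-to-tail)
    ``z`` ends within ``d`` of ``y``'s start: ``q > p`` and
    ``q + |z| - 1 <= p + d``.
``RELAXED`` (relaxed tandem)
    HH restricted to ``z`` occurrences before the next ``y`` occurrence.
``TANDEM``
    number of ``y`` occurrences whose *closest* following ``z`` occurrence
    falls inside the truncated window (no interleaving occurrence of either
    word between the counted pair).

All tree-based counters annotate leaf weights and propagate them bottom-up,
so one pass prices every second component ``z`` (every tree vertex)
simultaneously.  ``naive_count`` applies the definitions literally on
occurrence lists and serves as the independent oracle and the exhaustive
baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .index import SuffixIndex, TreeNode, build_index
from .sequences import SequenceSet

__all__ = [
    "Mode", "GappedFactorQuery", "CoocTable",
    "annotate_hh", "annotate_relaxed", "annotate_tandem",
    "annotate_th_exact", "query_th", "count_ht", "count", "naive_count",
]


class Mode(str, Enum):
    HH = "hh"
    TH = "th"
    HT = "ht"
    RELAXED_TANDEM = "relaxed"
    TANDEM = "tandem"


@dataclass(frozen=True)
class GappedFactorQuery:
    """A gapped-factor query: first component, second component, distance."""

    y: str
    z: str
    d: int
    mode: Mode = Mode.HH
    h: Optional[int] = None  # exact tail-to-head distance, TH only

    def __post_init__(self):
        if not self.y or not self.z:
            raise ValueError("components must be non-empty")
        if self.d < 0:
            raise ValueError("distance d must be >= 0")
        if self.h is not None and self.h < 0:
            raise ValueError("exact distance h must be >= 0")


@dataclass
class CoocTable:
    """Per-vertex co-occurrence counts for one first component.

    ``counts[node.id]`` is the index value for the pair
    ``(w(y_node), w(node))`` under the table's mode and distance; by class
    equivalence it is also the value for any word whose locus is ``node``.
    """

    index: SuffixIndex
    y_node: Optional[TreeNode]
    mode: Mode
    d: Optional[int]
    h: Optional[int]
    counts: list[int]

    def __getitem__(self, node: TreeNode) -> int:
        return self.counts[node.id]

    def count_word(self, z: str) -> int:
        node = self.index.locus(z)
        return 0 if node is None else self.counts[node.id]


def _occ_concat(index: SuffixIndex, node: TreeNode) -> list[int]:
    """Occurrence start positions of w(node) as sorted concat offsets."""
    sa = index._sa_f
    return sorted(sa[i] for i in range(node.sa_l, node.sa_r))


def _propagate(index: SuffixIndex, weights: list[int]) -> None:
    parent = index.parent_ids
    for nid in index.postorder:
        pid = parent[nid]
        if pid >= 0:
            weights[pid] += weights[nid]


def _truncated_windows(index: SuffixIndex, y_node: TreeNode, d: int,
                       truncate: bool) -> list[tuple[int, int]]:
    """(p, last) concat spans of the marking window after each y start.

    ``last`` is the last markable concat offset: record-end clipped, and —
    when ``truncate`` — cut before the next y occurrence (d' = min(d,
    p_{i+1} - p_i - 1) in the relaxed/tandem semantics).
    """
    occ = _occ_concat(index, y_node)
    rec = index.pos_record
    term = index.record_term
    spans = []
    for i, p in enumerate(occ):
        dd = d
        if truncate and i + 1 < len(occ) and rec[occ[i + 1]] == rec[p]:
            dd = min(d, occ[i + 1] - p - 1)
        last = min(p + dd, term[rec[p]] - 1)
        spans.append((p, last))
    return spans


def annotate_hh(index: SuffixIndex, y_node: TreeNode, d: int) -> CoocTable:
    """Basic head-to-head table: mark positions p+1 .. p+d after every
    occurrence of y, weight the corresponding leaves, sum bottom-up."""
    if d < 1:
        raise ValueError("head-to-head distance requires d >= 1")
    weights = [0] * index.n_nodes
    leaf_at = index.leaf_id_at
    for p, last in _truncated_windows(index, y_node, d, truncate=False):
        for q in range(p + 1, last + 1):
            weights[leaf_at[q]] += 1
    _propagate(index, weights)
    return CoocTable(index, y_node, Mode.HH, d, None, weights)


def annotate_relaxed(index: SuffixIndex, y_node: TreeNode, d: int) -> CoocTable:
    """Relaxed tandem table: as HH but the window stops before the next
    occurrence of y, so every z occurrence pairs with its closest y."""
    if d < 1:
        raise ValueError("relaxed tandem distance requires d >= 1")
    weights = [0] * index.n_nodes
    leaf_at = index.leaf_id_at
    for p, last in _truncated_windows(index, y_node, d, truncate=True):
        for q in range(p + 1, last + 1):
            weights[leaf_at[q]] += 1
    _propagate(index, weights)
    return CoocTable(index, y_node, Mode.RELAXED_TANDEM, d, None, weights)


def annotate_tandem(index: SuffixIndex, y_node: TreeNode, d: int) -> CoocTable:
    """Tandem table: relaxed marking, then for each window the marked
    leaves are visited in lexicographic (suffix array) order and the weight
    of the LCA of each consecutive pair is decremented.

    Under any vertex the marked leaves of one window occupy a contiguous
    block of that ordering, so after bottom-up propagation each window
    contributes exactly 1 to every vertex with at least one marked leaf
    below it: the count of y occurrences whose closest following z lies in
    the truncated window.  (Weights may go transiently negative at internal
    vertices before propagation.)
    """
    if d < 1:
        raise ValueError("tandem distance requires d >= 1")
    weights = [0] * index.n_nodes
    leaf_at = index.leaf_id_at
    nodes = index.nodes
    for p, last in _truncated_windows(index, y_node, d, truncate=True):
        leaf_ids = [leaf_at[q] for q in range(p + 1, last + 1)]
        for lid in leaf_ids:
            weights[lid] += 1
        leaf_ids.sort(key=lambda lid: nodes[lid].sa_l)
        for a, b in zip(leaf_ids, leaf_ids[1:]):
            anc = index.lca(nodes[a], nodes[b])
            weights[anc.id] -= 1
    _propagate(index, weights)
    return CoocTable(index, y_node, Mode.TANDEM, d, None, weights)


def annotate_th_exact(index: SuffixIndex, y_node: TreeNode, h: int) -> CoocTable:
    """Exact-distance tail-to-head table for the maximal word y = w(y_node):
    weight the leaf at p + |y| + h for every occurrence p of y."""
    if h < 0:
        raise ValueError("exact distance h must be >= 0")
    weights = [0] * index.n_nodes
    leaf_at = index.leaf_id_at
    rec = index.pos_record
    term = index.record_term
    wd = y_node.word_depth
    for p in _occ_concat(index, y_node):
        q = p + wd + h
        if q <= term[rec[p]] - 1:
            weights[leaf_at[q]] += 1
    _propagate(index, weights)
    return CoocTable(index, y_node, Mode.TH, None, h, weights)


def th_exact_query(index: SuffixIndex, y_prime: str, z_prime: str, h: int,
                   _cache: Optional[dict] = None) -> int:
    """Tail-to-head co-occurrences of (y', z') at exact gap h.

    Two cases against the maximal word y of y''s class: if |y'| + h > |y|
    the occurrences of y and z do not overlap and the exact-distance table
    of y is read at the adjusted gap |y'| + h - |y|; otherwise the count is
    the number of occurrences of the overlap concatenation
    y[1..|y'|+h] . z'.
    """
    alpha = index.locus(y_prime)
    beta = index.locus(z_prime)
    if alpha is None or beta is None:
        return 0
    y_max = index.word(alpha)
    k = len(y_prime) + h
    if k <= len(y_max):
        w = y_max[:k] + z_prime
        node = index.locus(w)
        return 0 if node is None else node.occurrence_count
    h_adj = k - len(y_max)
    if _cache is not None:
        key = (alpha.id, h_adj)
        table = _cache.get(key)
        if table is None:
            table = _cache[key] = annotate_th_exact(index, alpha, h_adj)
    else:
        table = annotate_th_exact(index, alpha, h_adj)
    return table[beta]


def query_th(index: SuffixIndex, y_prime: str, z_prime: str, d: int,
             d_min: int = 0, _cache: Optional[dict] = None) -> int:
    """Tail-to-head index of (y', z') summed over exact gaps d_min..d."""
    if d < 0 or d_min < 0 or d_min > d:
        raise ValueError("need 0 <= d_min <= d")
    return sum(th_exact_query(index, y_prime, z_prime, h, _cache=_cache)
               for h in range(d_min, d + 1))


def count_ht(index: SuffixIndex, y_node: TreeNode, d: int,
             exclude_within_y: bool = False,
             seqs: Optional[SequenceSet] = None) -> CoocTable:
    """Head-to-tail table via a generalized suffix tree over the windows
    x[p+1 .. p+d] following each occurrence of y (distinct end markers per
    window; clipped at record ends).

    For a window-tree vertex beta, the weighted leaf count of its subtree
    is the number of z = w(beta) occurrences that begin after p and end at
    or before p + d.  With ``exclude_within_y`` the leaves starting inside
    the source occurrence of y itself are not counted.
    """
    if d < 1:
        raise ValueError("head-to-tail distance requires d >= 1")
    seqs = seqs if seqs is not None else index.seqs
    rec = index.pos_record
    term = index.record_term
    wd = y_node.word_depth
    windows: list[str] = []
    offsets: list[int] = []  # window start offset relative to p (always 1)
    within_y_limit: list[int] = []  # 1-based window offsets <= this lie in y
    for p in _occ_concat(index, y_node):
        last = min(p + d, term[rec[p]] - 1)
        if last <= p:
            continue
        r = rec[p]
        local = index.pos_local[p]  # 1-based start of y in its record
        s = seqs.sequence(r)[local: local + (last - p)]
        windows.append(s)
        offsets.append(1)
        within_y_limit.append(wd - 1)
    if not windows:
        empty_idx = index  # no window: zero table over the main tree
        return CoocTable(empty_idx, y_node, Mode.HT, d, None,
                         [0] * empty_idx.n_nodes)
    wset = SequenceSet.from_strings(windows, alphabet=index.seqs.alphabet)
    widx = SuffixIndex(wset)
    weights = [0] * widx.n_nodes
    for node in widx.nodes:
        if node.is_leaf:
            j = widx.pos_local[node.suffix_start]  # 1-based offset in window
            w_i = widx.pos_record[node.suffix_start]
            if exclude_within_y and j <= within_y_limit[w_i]:
                continue
            weights[node.id] += 1
    _propagate(widx, weights)
    return CoocTable(widx, y_node, Mode.HT, d, None, weights)


def count(index: SuffixIndex, query: GappedFactorQuery) -> int:
    """Co-occurrence count for a single query, dispatched by mode.

    Non-maximal components are answered through their class
    representatives (equal counts by construction); tail-to-head queries go
    through the two-case exact-distance machinery, which also handles the
    non-equal overlap case.
    """
    ay = index.locus(query.y)
    az = index.locus(query.z)
    if ay is None or az is None:
        return 0
    mode = Mode(query.mode)
    if mode is Mode.TH:
        if query.h is not None:
            return th_exact_query(index, query.y, query.z, query.h)
        return query_th(index, query.y, query.z, query.d)
    if mode is Mode.HH:
        return annotate_hh(index, ay, query.d)[az]
    if mode is Mode.RELAXED_TANDEM:
        return annotate_relaxed(index, ay, query.d)[az]
    if mode is Mode.TANDEM:
        return annotate_tandem(index, ay, query.d)[az]
    if mode is Mode.HT:
        return count_ht(index, ay, query.d).count_word(query.z)
    raise ValueError(f"invalid mode {query.mode!r}")  # pragma: no cover


# ---------------------------------------------------------------- oracle


def _occ_lists(seqs: SequenceSet, w: str) -> list[list[int]]:
    out = []
    for _, s in seqs.records:
        out.append([i + 1 for i in range(len(s)) if s.startswith(w, i)])
    return out


def naive_count(x: SequenceSet | str, y: str, z: str, d: int,
                mode: Mode | str = Mode.HH, d_min: int = 0) -> int:
    """Literal application of the distance definitions on occurrence lists.

    The exhaustive-enumeration baseline and the testing oracle for every
    tree-based counter.  ``d_min`` applies to TH only (gap range
    [d_min, d]).
    """
    if isinstance(x, str):
        x = SequenceSet.from_strings(x)
    mode = Mode(mode)
    ys = _occ_lists(x, y)
    zs = _occ_lists(x, z)
    total = 0
    for yo, zo in zip(ys, zs):
        if mode is Mode.HH:
            total += sum(1 for p in yo for q in zo if 1 <= q - p <= d)
        elif mode is Mode.TH:
            total += sum(1 for p in yo for q in zo
                         if d_min <= q - (p + len(y)) <= d)
        elif mode is Mode.HT:
            total += sum(1 for p in yo for q in zo
                         if q > p and q + len(z) - 1 <= p + d)
        elif mode is Mode.RELAXED_TANDEM:
            for i, p in enumerate(yo):
                nxt = yo[i + 1] if i + 1 < len(yo) else None
                total += sum(1 for q in zo
                             if p < q <= p + d and (nxt is None or q < nxt))
        elif mode is Mode.TANDEM:
            for i, p in enumerate(yo):
                dd = d
                if i + 1 < len(yo):
                    dd = min(d, yo[i + 1] - p - 1)
                if any(p < q <= p + dd for q in zo):
                    total += 1
    return total
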