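"""Generalized suffix tree index with loci, occurrence lists and O(1) LCA.

The tree is built from a suffix array (numpy prefix-doubling) and its LCP
array (Kasai), then materialized as a compact trie by the classic stack
construction over LCP values.  Each record of the input gets a distinct
terminal marker, so no suffix — and hence no gapped-factor distance —
crosses a record boundary.

Terminology: the word ending exactly at a vertex alpha is ``w(alpha)`` and
alpha is its *proper locus*; the *locus* of any occurring word ``v`` is the
unique vertex alpha such that ``v`` is a prefix of ``w(alpha)`` while
``w(parent(alpha))`` is a proper prefix of ``v``.  All words sharing a locus
share the same set of 1-based start positions; the longest of them,
``w(alpha)``, is the class *representative* (maximal word).
"""

from __future__ import annotations

from typing import Iterator, Optional

import numpy as np

from .sequences import SequenceSet

__all__ = ["TreeNode", "SuffixIndex", "build_index"]


class TreeNode:
    """A vertex of the suffix tree.

    ``depth`` is the string depth of ``w(node)`` including the terminal
    marker for leaves; ``word_depth`` excludes it (the length of the longest
    proper word ending at the node).  ``ref`` is the start, in the
    concatenated text, of one suffix passing through the node, so the path
    label is ``text[ref : ref + depth]``.  ``weight`` is scratch storage for
    the counting annotations and is reset per first-component pass.
    """

    __slots__ = (
        "id", "parent", "children", "depth", "word_depth", "ref",
        "sa_l", "sa_r", "occurrence_count", "weight", "is_leaf",
        "suffix_start", "tree_token",
    )

    def __init__(self, depth: int, ref: int, is_leaf: bool = False,
                 suffix_start: int = -1):
        self.id = -1
        self.parent: Optional[TreeNode] = None
        self.children: dict[int, TreeNode] = {}
        self.depth = depth
        self.word_depth = depth
        self.ref = ref
        self.sa_l = -1
        self.sa_r = -1
        self.occurrence_count = 0
        self.weight = 0
        self.is_leaf = is_leaf
        self.suffix_start = suffix_start  # concat position of the leaf's suffix
        self.tree_token = -1

    @property
    def has_word_class(self) -> bool:
        """True iff some non-empty word has this vertex as proper locus.

        False for the root and for leaves reached by a bare terminal edge
        (their longest proper word already ends at the parent).
        """
        if self.parent is None:
            return False
        return self.word_depth > self.parent.word_depth

    def __repr__(self):  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else "node"
        return f"<{kind} id={self.id} depth={self.depth}>"


def _suffix_array(t: np.ndarray) -> np.ndarray:
    """Suffix array of an integer sequence by prefix doubling, O(n log^2 n)."""
    n = t.size
    if n == 1:
        return np.zeros(1, dtype=np.int64)
    rank = np.unique(t, return_inverse=True)[1].astype(np.int64)
    k = 1
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: n - k] = rank[k:]
        order = np.lexsort((key2, rank))
        r_o = rank[order]
        k_o = key2[order]
        changed = np.empty(n, dtype=np.int64)
        changed[0] = 0
        changed[1:] = (r_o[1:] != r_o[:-1]) | (k_o[1:] != k_o[:-1])
        new_rank = np.cumsum(changed)
        rank = np.empty(n, dtype=np.int64)
        rank[order] = new_rank
        if new_rank[-1] == n - 1:
            return order.astype(np.int64)
        k *= 2


def _lcp_kasai(t: list[int], sa: np.ndarray) -> list[int]:
    """LCP array: lcp[r] = longest common prefix of suffixes sa[r-1], sa[r]."""
    n = len(t)
    rank = [0] * n
    sa_list = [int(v) for v in sa]
    for r, i in enumerate(sa_list):
        rank[i] = r
    lcp = [0] * n
    h = 0
    for i in range(n):
        r = rank[i]
        if r > 0:
            j = sa_list[r - 1]
            while i + h < n and j + h < n and t[i + h] == t[j + h]:
                h += 1
            lcp[r] = h
            if h:
                h -= 1
        else:
            h = 0
    return lcp


class SuffixIndex:
    """Generalized suffix tree over a :class:`SequenceSet`.

    Attributes of note:

    ``nodes``
        All vertices in DFS order (``nodes[i].id == i``); leaves carry one
        text position each and internal nodes (except possibly the root)
        branch.
    ``leaf_map``
        ``(record id, 1-based position) -> leaf`` for every text position.
    ``postorder``
        Node ids with children before parents — the bottom-up annotation
        order used by the counting module.
    """

    def __init__(self, seqs: SequenceSet):
        self.seqs = seqs
        self._build_text()
        self._build_tree()
        self._finalize()
        self._build_lca()

    # -- construction -------------------------------------------------

    def _build_text(self) -> None:
        seqs = self.seqs
        self.symbols = sorted(seqs.alphabet)
        self.sym2code = {c: i + 1 for i, c in enumerate(self.symbols)}
        self.code2sym = {v: k for k, v in self.sym2code.items()}
        concat: list[int] = []
        pos_record: list[int] = []
        pos_local: list[int] = []
        record_start: list[int] = []
        record_term: list[int] = []
        for r, (_, seq) in enumerate(seqs.records):
            record_start.append(len(concat))
            for i, c in enumerate(seq):
                concat.append(self.sym2code[c])
                pos_record.append(r)
                pos_local.append(i + 1)
            record_term.append(len(concat))
            concat.append(-(r + 1))  # unique terminal, sorts before symbols
            pos_record.append(r)
            pos_local.append(len(seq) + 1)
        self.concat = concat
        self.pos_record = pos_record
        self.pos_local = pos_local
        self.record_start = record_start
        self.record_term = record_term  # concat index of each record's terminal
        self.n_positions = seqs.total_length

    def _build_tree(self) -> None:
        concat = self.concat
        t = np.asarray(concat, dtype=np.int64)
        sa = _suffix_array(t)
        lcp = _lcp_kasai(concat, sa)
        nrec = len(self.seqs.records)
        # terminal-only suffixes sort first (negative codes); drop them
        sa_f = [int(v) for v in sa[nrec:]]
        lcp_f = [0] + [lcp[nrec + i] for i in range(1, len(sa_f))]
        # concat index -> index of that record's terminal
        term_of = [self.record_term[r] for r in self.pos_record]

        root = TreeNode(depth=0, ref=sa_f[0] if sa_f else 0)
        stack = [root]
        for idx, pos in enumerate(sa_f):
            l = lcp_f[idx]
            leaf = TreeNode(depth=term_of[pos] - pos + 1, ref=pos,
                            is_leaf=True, suffix_start=pos)
            leaf.sa_l = idx
            leaf.sa_r = idx + 1
            last = None
            while stack[-1].depth > l:
                last = stack.pop()
            top = stack[-1]
            if top.depth == l:
                parent = top
            else:
                # split the edge top -> last with a new branching vertex
                parent = TreeNode(depth=l, ref=last.ref)
                key = concat[last.ref + top.depth]
                del top.children[key]
                top.children[key] = parent
                parent.parent = top
                parent.children[concat[last.ref + l]] = last
                last.parent = parent
                stack.append(parent)
            parent.children[concat[pos + parent.depth]] = leaf
            leaf.parent = parent
            stack.append(leaf)
        self.root = root
        self._sa_f = sa_f

    def _finalize(self) -> None:
        token = id(self)
        nodes: list[TreeNode] = []
        postorder: list[int] = []
        # iterative DFS assigning ids in preorder, collecting postorder
        stack: list[tuple[TreeNode, bool]] = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                postorder.append(node.id)
                if node.children:
                    node.sa_l = min(c.sa_l for c in node.children.values())
                    node.sa_r = max(c.sa_r for c in node.children.values())
                    node.occurrence_count = sum(
                        c.occurrence_count for c in node.children.values())
                continue
            node.id = len(nodes)
            node.tree_token = token
            node.word_depth = node.depth - 1 if node.is_leaf else node.depth
            if node.is_leaf:
                node.occurrence_count = 1
            nodes.append(node)
            stack.append((node, True))
            for child in reversed(list(node.children.values())):
                stack.append((child, False))
        self.nodes = nodes
        self.postorder = postorder
        self.parent_ids = [n.parent.id if n.parent is not None else -1
                           for n in nodes]
        # leaf lookup by concat position, and the user-facing leaf map
        self.leaf_id_at = [-1] * len(self.concat)
        self.leaf_map: dict[tuple[str, int], TreeNode] = {}
        for n in nodes:
            if n.is_leaf:
                self.leaf_id_at[n.suffix_start] = n.id
                r = self.pos_record[n.suffix_start]
                self.leaf_map[(self.seqs.ids[r],
                               self.pos_local[n.suffix_start])] = n

    def _build_lca(self) -> None:
        # Euler tour + sparse-table RMQ for O(1) LCA after O(n log n) prep
        tour: list[int] = []
        tdepth: list[int] = []
        first = [-1] * len(self.nodes)
        stack: list[tuple[TreeNode, int, Iterator[TreeNode]]] = [
            (self.root, 0, iter(list(self.root.children.values())))]
        tour.append(self.root.id)
        tdepth.append(0)
        first[self.root.id] = 0
        while stack:
            node, d, it = stack[-1]
            child = next(it, None)
            if child is None:
                stack.pop()
                if stack:
                    tour.append(stack[-1][0].id)
                    tdepth.append(stack[-1][1])
                continue
            tour.append(child.id)
            tdepth.append(d + 1)
            first[child.id] = len(tour) - 1
            stack.append((child, d + 1, iter(list(child.children.values()))))
        self._euler_tour = np.asarray(tour, dtype=np.int64)
        depth_arr = np.asarray(tdepth, dtype=np.int64)
        m = len(tour)
        levels = max(1, m.bit_length())
        sparse = [np.arange(m, dtype=np.int64)]
        for j in range(1, levels):
            half = 1 << (j - 1)
            prev = sparse[-1]
            if m - (1 << j) + 1 <= 0:
                break
            a = prev[: m - (1 << j) + 1]
            b = prev[half: half + m - (1 << j) + 1]
            sparse.append(np.where(depth_arr[a] <= depth_arr[b], a, b))
        self._rmq_sparse = sparse
        self._rmq_depth = depth_arr
        self._euler_first = first

    # -- queries ------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def word(self, node: TreeNode) -> str:
        """w(node): the maximal word with proper locus ``node`` (terminals
        excluded)."""
        return "".join(self.code2sym[self.concat[i]]
                       for i in range(node.ref, node.ref + node.word_depth))

    def locus(self, v: str) -> Optional[TreeNode]:
        """Locus of ``v``: the unique vertex whose path label first covers
        ``v``; ``None`` if ``v`` does not occur."""
        if not v:
            raise ValueError("locus of the empty word is undefined")
        codes = []
        for c in v:
            code = self.sym2code.get(c)
            if code is None:
                return None
            codes.append(code)
        concat = self.concat
        node = self.root
        depth = 0
        m = len(codes)
        while depth < m:
            child = node.children.get(codes[depth])
            if child is None:
                return None
            end = min(child.depth, m)
            for j in range(depth + 1, end):
                if concat[child.ref + j] != codes[j]:
                    return None
            if m <= child.word_depth:
                return child
            if m <= child.depth:
                # v would extend into a terminal marker: no real occurrence
                return None
            node = child
            depth = child.depth
        return node  # unreachable for non-empty v

    def representative(self, v: str) -> str:
        """Longest word sharing ``v``'s start positions (class maximal word)."""
        node = self.locus(v)
        if node is None:
            raise KeyError(f"word {v!r} does not occur in the indexed text")
        return self.word(node)

    def occurrences(self, node: TreeNode) -> list[tuple[int, int]]:
        """Sorted (record index, 1-based start) of w(node)'s occurrences."""
        out = [(self.pos_record[self._sa_f[i]],
                self.pos_local[self._sa_f[i]])
               for i in range(node.sa_l, node.sa_r)]
        out.sort()
        return out

    def start_positions(self, v: str) -> list[tuple[int, int]]:
        node = self.locus(v)
        return [] if node is None else self.occurrences(node)

    def lca(self, a: TreeNode, b: TreeNode) -> TreeNode:
        """Lowest common ancestor; w(lca) is the longest common prefix of
        w(a) and w(b)."""
        if a.tree_token != id(self) or b.tree_token != id(self):
            raise ValueError("nodes do not belong to this index")
        if a is b:
            return a
        i = self._euler_first[a.id]
        j = self._euler_first[b.id]
        if i > j:
            i, j = j, i
        span = j - i + 1
        k = span.bit_length() - 1
        sp = self._rmq_sparse[k]
        x = sp[i]
        y = sp[j - (1 << k) + 1]
        best = x if self._rmq_depth[x] <= self._rmq_depth[y] else y
        return self.nodes[self._euler_tour[best]]

    def words_of_length(self, k: int) -> dict[str, TreeNode]:
        """All distinct length-``k`` words in the text, mapped to their loci."""
        out: dict[str, TreeNode] = {}
        for node in self.nodes:
            if node.parent is None:
                continue
            if node.parent.word_depth < k <= node.word_depth:
                w = "".join(self.code2sym[self.concat[i]]
                            for i in range(node.ref, node.ref + k))
                out[w] = node
        return out

    def reset_weights(self) -> None:
        for n in self.nodes:
            n.weight = 0


def build_index(seqs: SequenceSet | str) -> SuffixIndex:
    """Build the generalized suffix tree index for a sequence set.

    Accepts a raw string for convenience (single DNA record).
    """
    if isinstance(seqs, str):
        seqs = SequenceSet.from_strings(seqs)
    return SuffixIndex(seqs)
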