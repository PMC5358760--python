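"""Percent-identity distances and neighbor-joining trees of element copies.

Given a multiple alignment of repeat copies (e.g. the orthologous intronic
MIRs of different species), pairwise distance is ``100 - percent identity``,
with gaps either excluded pairwise (``pairwise_deletion``, the default) or
counted as mismatches (``count_as_mismatch``). The unrooted tree is built by
canonical neighbor joining on that matrix: at each step the pair minimizing

    Q(i, j) = (n - 2) d(i, j) - sum_k d(i, k) - sum_k d(j, k)

is joined, branch lengths follow the standard split formula, ties go to the
lowest taxon-index pair, and negative branch lengths are clamped to zero
(the original value is logged). Branch lengths are in percent units because
the distances are.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

GAP_RULES = ("pairwise_deletion", "count_as_mismatch")


@dataclass
class AlignmentSet:
    """Named rows of one multiple alignment ('-' for gaps)."""

    sequences: dict[str, str]

    def __post_init__(self):
        if len(self.sequences) < 2:
            raise ValueError("alignment needs at least 2 sequences")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValueError("aligned sequences have unequal lengths")

    @property
    def names(self) -> list[str]:
        return list(self.sequences)


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("nonzero diagonal")
        if np.any(self.d < 0):
            raise ValueError("negative distances")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.taxa) + "\n")
            for name, row in zip(self.taxa, self.d):
                fh.write(name + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


def percent_identity_distance(
    aln: AlignmentSet, gap_rule: str = "pairwise_deletion"
) -> DistanceMatrix:
    """d(i, j) = 100 - percent identity over compared columns.

    ``pairwise_deletion`` compares only columns where neither row is gapped;
    ``count_as_mismatch`` compares all columns not gapped in both rows, with
    a gap opposite a base counting as a mismatch.
    """
    if gap_rule not in GAP_RULES:
        raise ValueError(f"gap_rule must be one of {GAP_RULES}")
    names = aln.names
    rows = [np.frombuffer(aln.sequences[n].upper().encode(), dtype="S1") for n in names]
    gap = np.bytes_(b"-")
    n = len(names)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        gi, gj = rows[i] == gap, rows[j] == gap
        if gap_rule == "pairwise_deletion":
            use = ~gi & ~gj
            matches = int(np.count_nonzero((rows[i] == rows[j]) & use))
        else:
            use = ~(gi & gj)
            matches = int(np.count_nonzero((rows[i] == rows[j]) & use))
        compared = int(np.count_nonzero(use))
        if compared == 0:
            raise ValueError(
                f"no comparable columns between {names[i]!r} and {names[j]!r}")
        identity = 100.0 * matches / compared
        d[i, j] = d[j, i] = 100.0 - identity
    return DistanceMatrix(names, d)


# ----------------------------------------------------------------- trees

@dataclass
class Node:
    name: str = ""
    children: list[tuple["Node", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Tree:
    """Unrooted tree stored with an arbitrary internal node as root (the
    final three-way join of neighbor joining)."""

    root: Node

    def leaf_names(self) -> set[str]:
        out = set()

        def walk(node):
            if node.is_leaf:
                out.add(node.name)
            for ch, _ in node.children:
                walk(ch)

        walk(self.root)
        return out

    def to_newick(self) -> str:
        def fmt(node, length=None):
            if node.is_leaf:
                body = node.name
            else:
                body = "(" + ",".join(fmt(ch, ln) for ch, ln in node.children) + ")"
            return body if length is None else f"{body}:{length:.10g}"

        return fmt(self.root) + ";"

    def splits(self) -> dict[frozenset, float]:
        """Map each edge's leaf bipartition (as the smaller-side frozenset,
        ties by sorted order) to its branch length. Trivial splits (single
        leaves) are included; the root's edges between its three children are
        each their own split."""
        leaves = frozenset(self.leaf_names())
        out: dict[frozenset, float] = {}

        def below(node) -> frozenset:
            if node.is_leaf:
                return frozenset([node.name])
            return frozenset().union(*(below(ch) for ch, _ in node.children))

        def walk(node):
            for ch, ln in node.children:
                side = below(ch)
                other = leaves - side
                key = min(side, other, key=lambda s: (len(s), sorted(s)))
                out[key] = out.get(key, 0.0) + ln
                walk(ch)

        walk(self.root)
        return out

    def topology(self) -> set[frozenset]:
        """Non-trivial bipartitions only — the unrooted topology."""
        n = len(self.leaf_names())
        return {s for s in self.splits() if 1 < len(s) < n - 1}


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Canonical neighbor joining with deterministic tie-breaking.

    Raises on fewer than 3 taxa or an invalid (asymmetric/negative) matrix —
    matrix validity is enforced by :class:`DistanceMatrix` itself.
    """
    n0 = len(dm.taxa)
    if n0 < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = dm.d.astype(float).copy()
    nodes: list[Node] = [Node(name=t) for t in dm.taxa]

    while len(nodes) > 3:
        n = len(nodes)
        r = d.sum(axis=1)
        q = (n - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        iu = np.triu_indices(n, k=1)
        qt = np.full_like(q, np.inf)
        qt[iu] = q[iu]
        # argmin over the upper triangle scans row-major, so the first
        # minimum is the lowest (i, j) pair — the documented tie-break
        i, j = np.unravel_index(int(np.argmin(qt)), qt.shape)

        dij = d[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (n - 2))
        lj = dij - li
        li, lj = _clamp(li), _clamp(lj)
        new = Node(children=[(nodes[i], li), (nodes[j], lj)])

        dnew = 0.5 * (d[i, :] + d[j, :] - dij)
        keep = [k for k in range(n) if k not in (i, j)]
        d2 = np.empty((n - 1, n - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = dnew[keep]
        d2[-1, -1] = 0.0
        d = d2
        nodes = [nodes[k] for k in keep] + [new]

    # final three-way join (closed form for 3 taxa)
    (a, b, c), dd = nodes, d
    la = _clamp(0.5 * (dd[0, 1] + dd[0, 2] - dd[1, 2]))
    lb = _clamp(0.5 * (dd[0, 1] + dd[1, 2] - dd[0, 2]))
    lc = _clamp(0.5 * (dd[0, 2] + dd[1, 2] - dd[0, 1]))
    return Tree(Node(children=[(a, la), (b, lb), (c, lc)]))


def _clamp(x: float) -> float:
    if x < 0:
        log.info("negative branch length %.6g clamped to 0", x)
        return 0.0
    return float(x)


def write_newick(tree: Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


def read_newick(path_or_string: str) -> Tree:
    """Parse a Newick string (or file path ending in .nwk/.newick/.tree)."""
    s = path_or_string
    if not s.rstrip().endswith(";"):
        with open(s) as fh:
            s = fh.read()
    return Tree(_parse_newick(s.strip().rstrip(";")))


def _parse_newick(s: str) -> Node:
    pos = 0

    def parse() -> tuple[Node, float | None]:
        nonlocal pos
        node = Node()
        if s[pos] == "(":
            pos += 1
            while True:
                child, ln = parse()
                node.children.append((child, 0.0 if ln is None else ln))
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
        # label
        start = pos
        while pos < len(s) and s[pos] not in ":,()":
            pos += 1
        node.name = s[start:pos].strip()
        length = None
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",()":
                pos += 1
            length = float(s[start:pos])
        return node, length

    node, _ = parse()
    return node
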