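"""Dispersal-vicariance (DIVA) ancestral-area reconstruction.

Event-based parsimony over geographic ranges coded as nonempty subsets
of a small fixed alphabet of areas (at most 8; the worked alphabet is
A-D).  Along a branch, a dispersal adds one area and an extinction
removes one area, each at cost 1.  At a node, a single-area range
duplicates into both daughters for free; a multi-area range splits by
vicariance into any ordered pair of nonempty disjoint subsets covering
it, also for free.  The reconstruction minimizes the total number of
dispersal + extinction events over the tree (a Sankoff-style dynamic
program over all nonempty subsets), and the traceback retains every
range that occurs in at least one globally optimal scenario.

S-DIVA-style node support summarizes reconstructions across a sample of
trees: at each clade of a reference tree, co-optimal ranges of each
sample tree containing that clade share weight 1/|co-optimal set|, and
frequencies are normalized over the trees containing the clade.  The
reference tree is typically the greedy all-compatible consensus of the
sample.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy

__all__ = [
    "AreaAlphabet",
    "TreeNode",
    "PhyloTree",
    "RangeCodingError",
    "TreeError",
    "parse_newick",
    "parse_tree_sample",
    "parse_ranges",
    "DivaReconstruction",
    "diva_reconstruct",
    "all_compatible_consensus",
    "NodeSupport",
    "SdivaSupport",
    "sdiva_support",
]

_INF = float("inf")


class TreeError(ValueError):
    """Invalid tree input (non-binary, duplicate or mismatched tips)."""


class RangeCodingError(ValueError):
    """Invalid area coding input."""


class AreaAlphabet:
    """Ordered alphabet of single-character area labels (bit-set coding)."""

    def __init__(self, labels: str = "ABCD"):
        if not 2 <= len(labels) <= 8:
            raise RangeCodingError("between 2 and 8 areas are supported")
        if len(set(labels)) != len(labels):
            raise RangeCodingError(f"duplicate area labels in {labels!r}")
        self.labels = labels
        self._index = {a: i for i, a in enumerate(labels)}

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def full_mask(self) -> int:
        return (1 << len(self.labels)) - 1

    def parse(self, text: str) -> int:
        """Range string like ``"AB"`` to a bit mask."""
        mask = 0
        for ch in text.strip():
            if ch not in self._index:
                raise RangeCodingError(
                    f"unknown area {ch!r}; alphabet is {self.labels!r}"
                )
            mask |= 1 << self._index[ch]
        if mask == 0:
            raise RangeCodingError("a range must contain at least one area")
        return mask

    def format(self, mask: int) -> str:
        """Bit mask back to a canonical range string."""
        return "".join(a for i, a in enumerate(self.labels) if mask >> i & 1)


# --- trees -----------------------------------------------------------------

class TreeNode:
    """Rooted tree node; a leaf carries a label, internals carry children."""

    __slots__ = ("label", "children")

    def __init__(self, label: str | None = None,
                 children: list["TreeNode"] | None = None):
        self.label = label
        self.children = children or []

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """Rooted strictly binary tree with unique tip labels."""

    def __init__(self, root: TreeNode):
        self.root = root
        tips = []
        for node in self.postorder():
            if node.is_leaf:
                if not node.label:
                    raise TreeError("unlabelled tip")
                tips.append(node.label)
            elif len(node.children) != 2:
                raise TreeError(
                    f"non-binary node with {len(node.children)} children; "
                    "DIVA input must be strictly bifurcating"
                )
        if len(set(tips)) != len(tips):
            raise TreeError("duplicate tip labels")
        self._tips = tips

    def tips(self) -> list[str]:
        return list(self._tips)

    def postorder(self):
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def clade_map(self) -> dict[int, frozenset]:
        """id(node) -> tip set, for every node."""
        clades: dict[int, frozenset] = {}
        for node in self.postorder():
            if node.is_leaf:
                clades[id(node)] = frozenset([node.label])
            else:
                clades[id(node)] = frozenset().union(
                    *(clades[id(c)] for c in node.children)
                )
        return clades

    def internal_clades(self) -> list[frozenset]:
        """Tip sets of internal nodes (root included), postorder."""
        clades = self.clade_map()
        return [clades[id(n)] for n in self.postorder() if not n.is_leaf]

    def to_newick(self) -> str:
        def rec(node: TreeNode) -> str:
            if node.is_leaf:
                return node.label
            return "(" + ",".join(rec(c) for c in node.children) + ")"
        return rec(self.root) + ";"


def _from_dendropy(tree: dendropy.Tree) -> PhyloTree:
    def rec(dnode) -> TreeNode:
        children = dnode.child_nodes()
        if not children:
            label = dnode.taxon.label if dnode.taxon else dnode.label
            return TreeNode(label=label)
        return TreeNode(children=[rec(c) for c in children])
    return PhyloTree(rec(tree.seed_node))


def parse_newick(text: str) -> PhyloTree:
    """Parse one newick tree; multifurcations are rejected."""
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:
        raise TreeError(f"cannot parse newick: {exc}") from exc
    return _from_dendropy(tree)


def parse_tree_sample(text: str) -> list[PhyloTree]:
    """Parse a tree sample: newick (one per line) or a nexus trees block."""
    schema = "nexus" if text.lstrip().upper().startswith("#NEXUS") else "newick"
    try:
        trees = dendropy.TreeList.get(data=text, schema=schema,
                                      preserve_underscores=True)
    except Exception as exc:
        raise TreeError(f"cannot parse tree sample: {exc}") from exc
    if not trees:
        raise TreeError("empty tree sample")
    return [_from_dendropy(t) for t in trees]


def parse_ranges(text: str, alphabet: AreaAlphabet) -> dict[str, int]:
    """Parse a TSV coding table ``taxon<TAB>range`` into taxon -> bit mask."""
    ranges: dict[str, int] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise RangeCodingError(f"line {lineno}: expected 'taxon<TAB>range'")
        taxon, coded = parts[0].strip(), parts[1]
        if taxon in ranges:
            raise RangeCodingError(f"line {lineno}: duplicate taxon {taxon!r}")
        ranges[taxon] = alphabet.parse(coded)
    if not ranges:
        raise RangeCodingError("empty range table")
    return ranges


# --- DIVA dynamic program --------------------------------------------------

def _popcount(x: int) -> int:
    return bin(x).count("1")


def _transform_cost(inherited: int, realized: int) -> int:
    """Dispersals (areas gained) + extinctions (areas lost) along a branch."""
    return _popcount(realized & ~inherited) + _popcount(inherited & ~realized)


def _splits(mask: int) -> list[tuple[int, int]]:
    """Allowed inheritance pairs at a node with range ``mask``.

    A single area duplicates into both daughters; a wider range splits
    by vicariance into ordered pairs of nonempty disjoint subsets
    covering it.
    """
    if mask & (mask - 1) == 0:  # single area
        return [(mask, mask)]
    out = []
    sub = (mask - 1) & mask
    while sub:
        out.append((sub, mask ^ sub))
        sub = (sub - 1) & mask
    return out


@dataclass
class DivaReconstruction:
    """Optimal ancestral ranges per internal node and the minimal event cost."""

    alphabet: AreaAlphabet
    min_cost: int
    # internal-node clade (tip frozenset) -> frozenset of optimal range strings
    node_ranges: dict[frozenset, frozenset] = field(default_factory=dict)

    def root_ranges(self, tips: frozenset) -> frozenset:
        return self.node_ranges[tips]


def diva_reconstruct(tree: PhyloTree, ranges: dict[str, int] | dict[str, str],
                     alphabet: AreaAlphabet,
                     max_areas: int | None = None) -> DivaReconstruction:
    """Minimal-event DIVA reconstruction on one binary tree.

    ``ranges`` maps every tip label to its observed range (bit mask or
    range string).  ``max_areas`` optionally caps the size of ancestral
    ranges (observed tip ranges are always allowed).  Returns the global
    minimum number of dispersal + extinction events and, per internal
    node, every range occurring in at least one globally optimal
    reconstruction.
    """
    if max_areas is not None and max_areas < 1:
        raise ValueError("max_areas must be >= 1")
    masks: dict[str, int] = {}
    for tip in tree.tips():
        if tip not in ranges:
            raise RangeCodingError(f"tip {tip!r} missing from the range table")
        value = ranges[tip]
        masks[tip] = alphabet.parse(value) if isinstance(value, str) else value
        if masks[tip] == 0:
            raise RangeCodingError(f"tip {tip!r} has an empty range")

    full = alphabet.full_mask
    cap = len(alphabet.labels) if max_areas is None else max_areas
    states = [m for m in range(1, full + 1) if _popcount(m) <= cap]
    all_masks = range(1, full + 1)

    # Bottom-up: cost[node][X] = cheapest cost of the subtree given the
    # node's realized range is X; down[node][I] = cheapest cost of the
    # branch to `node` plus its subtree given the inherited range is I.
    nodes = list(tree.postorder())
    cost: dict[int, dict[int, float]] = {}
    down: dict[int, dict[int, float]] = {}
    for node in nodes:
        if node.is_leaf:
            c = {m: _INF for m in all_masks}
            c[masks[node.label]] = 0.0
        else:
            left, right = node.children
            c = {m: _INF for m in all_masks}
            for x in states:
                best = _INF
                for i_l, i_r in _splits(x):
                    v = down[id(left)][i_l] + down[id(right)][i_r]
                    if v < best:
                        best = v
                c[x] = best
        cost[id(node)] = c
        d = {}
        for i in all_masks:
            d[i] = min(_transform_cost(i, realized) + c[realized]
                       for realized in all_masks if c[realized] < _INF)
        down[id(node)] = d

    root = tree.root
    min_cost = min(cost[id(root)].values())
    if min_cost == _INF:
        raise RangeCodingError("no feasible reconstruction")

    # Traceback: mark every (internal node, range) pair that occurs in
    # some globally optimal scenario.
    clades = tree.clade_map()
    optimal: dict[int, set[int]] = {id(n): set() for n in nodes if not n.is_leaf}
    root_opt = {x for x, v in cost[id(root)].items() if v == min_cost}
    optimal[id(root)] = set(root_opt)
    stack = [(root, x) for x in root_opt]
    seen = set((id(root), x) for x in root_opt)
    while stack:
        node, x = stack.pop()
        left, right = node.children
        target = cost[id(node)][x]
        for i_l, i_r in _splits(x):
            if down[id(left)][i_l] + down[id(right)][i_r] != target:
                continue
            for child, inherited in ((left, i_l), (right, i_r)):
                d_target = down[id(child)][inherited]
                for realized, c_val in cost[id(child)].items():
                    if c_val < _INF and \
                            _transform_cost(inherited, realized) + c_val == d_target:
                        if child.is_leaf:
                            continue
                        key = (id(child), realized)
                        if key not in seen:
                            seen.add(key)
                            optimal[id(child)].add(realized)
                            stack.append((child, realized))

    node_ranges = {
        clades[nid]: frozenset(alphabet.format(m) for m in opts)
        for nid, opts in optimal.items()
    }
    return DivaReconstruction(alphabet=alphabet, min_cost=int(min_cost),
                              node_ranges=node_ranges)


# --- greedy all-compatible consensus --------------------------------------

def _compatible(a: frozenset, b: frozenset) -> bool:
    return a <= b or b <= a or not (a & b)


def all_compatible_consensus(trees: list[PhyloTree]) -> PhyloTree:
    """Greedy all-compatible consensus of a sample of rooted binary trees.

    Clades are counted across the sample and added in decreasing
    frequency (ties broken by lexicographic tip-set order) whenever
    compatible with the clades already accepted; remaining polytomies
    are resolved deterministically by repeatedly joining the two
    children with the smallest minimum tip labels.
    """
    if not trees:
        raise TreeError("empty tree sample")
    tip_set = frozenset(trees[0].tips())
    counts: dict[frozenset, int] = {}
    for tree in trees:
        if frozenset(tree.tips()) != tip_set:
            raise TreeError("trees in the sample have different tip sets")
        for clade in tree.internal_clades():
            if clade != tip_set:
                counts[clade] = counts.get(clade, 0) + 1

    accepted: list[frozenset] = []
    for clade in sorted(counts, key=lambda c: (-counts[c], tuple(sorted(c)))):
        if all(_compatible(clade, other) for other in accepted):
            accepted.append(clade)

    # Build the tree from the accepted clade hierarchy.
    nodes: dict[frozenset, TreeNode] = {
        frozenset([t]): TreeNode(label=t) for t in tip_set
    }
    hierarchy = sorted(accepted + [tip_set], key=len)
    for clade in hierarchy:
        if clade not in nodes:
            nodes[clade] = TreeNode()
    for clade in hierarchy:
        # direct children: maximal nested clades/singletons, greedily by size
        remaining = set(clade)
        children: list[frozenset] = []
        for cand in sorted((c for c in nodes if c < clade),
                           key=lambda c: (-len(c), tuple(sorted(c)))):
            if cand <= remaining:
                children.append(cand)
                remaining -= cand
        node = nodes[clade]
        node.children = [nodes[c] for c in sorted(children,
                                                  key=lambda c: min(c))]
        # binarize: join the two children with the smallest min labels
        while len(node.children) > 2:
            node.children.sort(key=lambda ch: _min_tip(ch))
            a = node.children.pop(0)
            b = node.children.pop(0)
            joined = TreeNode(children=[a, b])
            node.children.insert(0, joined)
    return PhyloTree(nodes[tip_set])


def _min_tip(node: TreeNode) -> str:
    while not node.is_leaf:
        node = min(node.children, key=_min_tip)
    return node.label


# --- S-DIVA node support ---------------------------------------------------

@dataclass
class NodeSupport:
    """Range frequencies at one reference clade across the tree sample."""

    n_trees: int
    frequencies: dict[str, float]

    @property
    def has_support(self) -> bool:
        return self.n_trees > 0

    def lumped(self, threshold: float = 0.05) -> dict[str, float]:
        """Presentation map with ranges below ``threshold`` lumped into ``"*"``."""
        out: dict[str, float] = {}
        rest = 0.0
        for rng, freq in sorted(self.frequencies.items(),
                                key=lambda kv: (-kv[1], kv[0])):
            if freq < threshold:
                rest += freq
            else:
                out[rng] = freq
        if rest > 0:
            out["*"] = rest
        return out


@dataclass
class SdivaSupport:
    """Per-clade range support for a reference tree over a tree sample."""

    alphabet: AreaAlphabet
    n_sample: int
    supports: dict[frozenset, NodeSupport]


def sdiva_support(reference: PhyloTree, sample: list[PhyloTree],
                  ranges: dict[str, int] | dict[str, str],
                  alphabet: AreaAlphabet,
                  max_areas: int | None = None) -> SdivaSupport:
    """S-DIVA-style per-node range frequencies across a tree sample.

    For every sample tree containing a reference clade, each co-optimal
    range at that clade receives weight 1/|co-optimal set|; frequencies
    are normalized by the number of sample trees containing the clade.
    Clades absent from every sample tree are flagged as unsupported
    (``n_trees == 0``) rather than zero-filled.
    """
    if not sample:
        raise TreeError("empty tree sample")
    ref_tips = frozenset(reference.tips())
    for tree in sample:
        if frozenset(tree.tips()) != ref_tips:
            raise TreeError("sample tree tip set differs from the reference")

    ref_clades = reference.internal_clades()
    acc: dict[frozenset, dict[str, float]] = {c: {} for c in ref_clades}
    counts: dict[frozenset, int] = {c: 0 for c in ref_clades}
    for tree in sample:
        rec = diva_reconstruct(tree, ranges, alphabet, max_areas=max_areas)
        for clade in ref_clades:
            opts = rec.node_ranges.get(clade)
            if opts is None:
                continue
            counts[clade] += 1
            w = 1.0 / len(opts)
            bucket = acc[clade]
            for rng in opts:
                bucket[rng] = bucket.get(rng, 0.0) + w

    supports = {}
    for clade in ref_clades:
        n = counts[clade]
        freqs = {rng: w / n for rng, w in acc[clade].items()} if n else {}
        supports[clade] = NodeSupport(n_trees=n, frequencies=freqs)
    return SdivaSupport(alphabet=alphabet, n_sample=len(sample),
                        supports=supports)
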