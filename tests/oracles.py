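"""Independent brute-force oracles used to validate the optimizers.

These deliberately avoid the implementation's data structures and
shortcuts: the pairing oracle enumerates all (2n-1)!! perfect matchings
and the range-reconstruction oracle enumerates all assignments of
ranges to internal nodes, so their answers are forced by the problem
definitions alone.
"""

from __future__ import annotations

import itertools

QUANTUM = 1e-12


def enumerate_matchings(items):
    """All perfect matchings of a list, as lists of index pairs."""
    if not items:
        yield []
        return
    first = items[0]
    for k in range(1, len(items)):
        rest = items[1:k] + items[k + 1:]
        for sub in enumerate_matchings(rest):
            yield [(first, items[k])] + sub


def brute_force_pairing(chroms, weights=(1.0, 1.0)):
    """Minimum-cost pairing by exhaustive enumeration.

    Returns (integer quantized cost, canonical pairing) where the
    canonical pairing is the lexicographically smallest list of sorted
    id pairs among all cost-minimal matchings.
    """
    chroms = sorted(chroms, key=lambda m: m.chromosome_id)
    mean_len = sum(m.total_length for m in chroms) / len(chroms)
    w_len, w_ci = weights

    def cost(i, j):
        a, b = chroms[i], chroms[j]
        d = (w_len * abs(a.total_length - b.total_length) / mean_len
             + w_ci * abs(a.centromeric_index - b.centromeric_index) / 50.0)
        return round(d / QUANTUM)

    best_cost = None
    best_pairing = None
    for matching in enumerate_matchings(list(range(len(chroms)))):
        total = sum(cost(i, j) for i, j in matching)
        canonical = sorted(
            tuple(sorted((chroms[i].chromosome_id, chroms[j].chromosome_id)))
            for i, j in matching
        )
        if best_cost is None or total < best_cost or \
                (total == best_cost and canonical < best_pairing):
            best_cost = total
            best_pairing = canonical
    return best_cost, best_pairing


def brute_force_diva(tree, tip_ranges, areas):
    """Exhaustive minimal-event reconstruction.

    ``tip_ranges`` maps tip label -> frozenset of area labels; ``areas``
    is the full iterable of labels.  Returns (min cost, dict clade ->
    set of frozensets optimal at that node).
    """
    areas = list(areas)
    subsets = [frozenset(c) for r in range(1, len(areas) + 1)
               for c in itertools.combinations(areas, r)]

    clades = tree.clade_map()
    internals = [n for n in tree.postorder() if not n.is_leaf]

    def transform(inherited, realized):
        return len(realized - inherited) + len(inherited - realized)

    def splits(mask):
        if len(mask) == 1:
            return [(mask, mask)]
        out = []
        members = sorted(mask)
        for r in range(1, len(members)):
            for combo in itertools.combinations(members, r):
                left = frozenset(combo)
                out.append((left, mask - left))
        return out

    def node_cost(x, child_ranges):
        return min(
            transform(i_l, child_ranges[0]) + transform(i_r, child_ranges[1])
            for i_l, i_r in splits(x)
        )

    best = None
    optimal = {clades[id(n)]: set() for n in internals}
    for assignment in itertools.product(subsets, repeat=len(internals)):
        ranges = {id(n): a for n, a in zip(internals, assignment)}
        for n in tree.postorder():
            if n.is_leaf:
                ranges[id(n)] = tip_ranges[n.label]
        total = 0
        for n in internals:
            kids = [ranges[id(c)] for c in n.children]
            total += node_cost(ranges[id(n)], kids)
        if best is None or total < best:
            best = total
            optimal = {clades[id(n)]: {ranges[id(n)]} for n in internals}
        elif total == best:
            for n in internals:
                optimal[clades[id(n)]].add(ranges[id(n)])
    return best, optimal
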