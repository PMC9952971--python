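"""Synthetic inputs with known truth for every stage of the pipeline.

Two families of generators:

* noisy multi-plate chromosome measurements from a known true haploid
  complement (multiplicative lognormal arm noise plus a per-plate
  condensation factor), emulating measurements taken from ~10 metaphase
  spreads of one organism;
* random Yule trees and per-branch dispersal/extinction range evolution
  over a small area alphabet, emulating coded tip distributions with
  known ancestral ranges.

All generators are pure functions of their parameters and seed.

Two packaged truth complements mirror the published comparative
karyotypes of the two *Bentinckia* species: a "condapanna-like" set of
15 metacentric pairs (2n = 30) and a "nicobarica-like" set of 9 median
+ 7 submedian pairs (2n = 32).  Their arm lengths were solved (offline,
then frozen here) so that the noiseless pipeline reproduces the
published THCL, CV_CL, CV_CI, M_CA, S, L and R to two decimals; they
are synthetic complements consistent with those summary statistics, not
the authors' raw measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ancestral_ranges import AreaAlphabet, PhyloTree, TreeNode
from .measurement_io import ChromosomeMeasurement, MeasurementTable

__all__ = [
    "TrueKaryotype",
    "RangeSimParams",
    "condapanna_like_truth",
    "nicobarica_like_truth",
    "simulate_measurements",
    "simulate_yule_tree",
    "simulate_range_evolution",
]


@dataclass(frozen=True)
class TrueKaryotype:
    """True haploid complement: (short_arm, long_arm) pairs in µm."""

    arms: tuple[tuple[float, float], ...]

    def __post_init__(self):
        if not self.arms:
            raise ValueError("a true karyotype needs at least one chromosome")
        for s, l in self.arms:
            if not (0 < s <= l):
                raise ValueError(f"arms must satisfy 0 < short <= long, got ({s}, {l})")

    @property
    def n(self) -> int:
        return len(self.arms)

    @property
    def total_lengths(self) -> tuple[float, ...]:
        return tuple(s + l for s, l in self.arms)


# 15 metacentric pairs, lengths 1.48-3.00 µm summing to 34.04 µm
# (2n = 30); solved so the noiseless summary matches the published
# B. condapanna column to 2 d.p. (except MCL and the Stebbins digit,
# which are internally inconsistent in the source table).
_CONDAPANNA_ARMS = (
    (1.1482, 1.8518), (1.0871, 1.7382), (1.0384, 1.6324), (1.0046, 1.5411),
    (0.9851, 1.4656), (0.9777, 1.4039), (0.9788, 1.3519), (0.9834, 1.3048),
    (0.9863, 1.2574), (0.9817, 1.2048), (0.9641, 1.1430), (0.9286, 1.0690),
    (0.8726, 0.9814), (0.7966, 0.8815), (0.7056, 0.7744),
)

# 9 m + 7 sm pairs, lengths 0.91-2.30 µm summing to 25.83 µm (2n = 32),
# matching the published B. nicobarica column the same way.
_NICOBARICA_ARMS = (
    (1.0596, 1.2404), (0.8125, 1.3954), (0.9510, 1.1654), (0.7455, 1.2802),
    (0.8479, 1.0879), (0.6607, 1.1856), (0.7536, 1.0032), (0.5814, 1.0855),
    (0.6619, 0.9144), (0.6121, 0.8725), (0.4728, 0.9188), (0.5251, 0.7722),
    (0.3973, 0.8044), (0.4398, 0.6653), (0.3240, 0.6837), (0.3566, 0.5534),
)


def condapanna_like_truth() -> TrueKaryotype:
    """15 metacentric pairs spanning 1.48-3.00 µm (2n = 30)."""
    return TrueKaryotype(arms=_CONDAPANNA_ARMS)


def nicobarica_like_truth() -> TrueKaryotype:
    """9 median + 7 submedian pairs spanning 0.91-2.30 µm (2n = 32)."""
    return TrueKaryotype(arms=_NICOBARICA_ARMS)


def simulate_measurements(truth: TrueKaryotype, n_plates: int = 10,
                          noise_sigma: float = 0.03,
                          plate_scale_sigma: float = 0.05,
                          seed: int = 0) -> MeasurementTable:
    """Simulate a multi-plate measurement table from a true complement.

    Each plate draws one condensation factor ~ lognormal(0,
    ``plate_scale_sigma``); each of the two homolog copies of each true
    chromosome has each arm multiplied by the plate factor times an
    independent lognormal(0, ``noise_sigma``) measurement error.  Row
    order within a plate is shuffled deterministically by ``seed``.
    """
    if n_plates < 1:
        raise ValueError("n_plates must be >= 1")
    if noise_sigma < 0 or plate_scale_sigma < 0:
        raise ValueError("noise sigmas must be >= 0")
    rng = np.random.default_rng(seed)
    measurements: list[ChromosomeMeasurement] = []
    for p in range(1, n_plates + 1):
        plate_id = f"P{p}"
        factor = float(rng.lognormal(0.0, plate_scale_sigma)) \
            if plate_scale_sigma > 0 else 1.0
        rows = []
        for k, (s_true, l_true) in enumerate(truth.arms, start=1):
            for copy in ("a", "b"):
                noise_s = float(rng.lognormal(0.0, noise_sigma)) \
                    if noise_sigma > 0 else 1.0
                noise_l = float(rng.lognormal(0.0, noise_sigma)) \
                    if noise_sigma > 0 else 1.0
                s = s_true * factor * noise_s
                l = l_true * factor * noise_l
                if s > l:
                    s, l = l, s
                rows.append(ChromosomeMeasurement(
                    plate_id=plate_id, chromosome_id=f"c{k:02d}{copy}",
                    short_arm=s, long_arm=l,
                ))
        order = rng.permutation(len(rows))
        measurements.extend(rows[i] for i in order)
    return MeasurementTable(measurements)


def simulate_yule_tree(n_tips: int, seed: int = 0) -> PhyloTree:
    """Random rooted binary tree by uniform bifurcation of tip lineages.

    Starting from a two-tip tree, a uniformly chosen extant tip is
    split until ``n_tips`` tips exist; tip labels ``t1..tn`` are then
    assigned in seeded random order.
    """
    if n_tips < 2:
        raise ValueError("a tree needs at least 2 tips")
    rng = np.random.default_rng(seed)
    root = TreeNode(children=[TreeNode(), TreeNode()])
    tips = list(root.children)
    while len(tips) < n_tips:
        idx = int(rng.integers(len(tips)))
        node = tips.pop(idx)
        node.children = [TreeNode(), TreeNode()]
        tips.extend(node.children)
    labels = [f"t{i + 1}" for i in range(n_tips)]
    for tip, lab in zip(tips, (labels[i] for i in rng.permutation(n_tips))):
        tip.label = lab
    return PhyloTree(root)


@dataclass(frozen=True)
class RangeSimParams:
    """Per-branch dispersal/extinction simulation settings."""

    dispersal_rate: float = 0.05   # expected dispersal events per branch
    extinction_rate: float = 0.05  # expected extinction events per branch
    alphabet: AreaAlphabet = field(default_factory=AreaAlphabet)
    root_range: str = "A"
    seed: int = 0

    def __post_init__(self):
        if self.dispersal_rate < 0 or self.extinction_rate < 0:
            raise ValueError("event rates must be >= 0")
        self.alphabet.parse(self.root_range)  # validates nonempty, in alphabet


def simulate_range_evolution(tree: PhyloTree, params: RangeSimParams,
                             ) -> tuple[dict[str, int], dict[frozenset, int]]:
    """Evolve ranges down a tree by per-branch dispersal/extinction events.

    The root starts at ``params.root_range``; along each branch a
    Poisson(``dispersal_rate``) number of dispersals each add one
    uniformly chosen absent area and a Poisson(``extinction_rate``)
    number of extinctions each remove one uniformly chosen present area
    (never emptying the range); event order within a branch is
    randomized.  Returns the tip coding table (tip -> mask) and the true
    range of every node keyed by clade tip set (root included).
    """
    rng = np.random.default_rng(params.seed)
    alphabet = params.alphabet
    n_areas = len(alphabet)
    clades = tree.clade_map()
    tip_ranges: dict[str, int] = {}
    truth: dict[frozenset, int] = {}

    def evolve(mask: int) -> int:
        n_disp = int(rng.poisson(params.dispersal_rate))
        n_ext = int(rng.poisson(params.extinction_rate))
        events = ["d"] * n_disp + ["e"] * n_ext
        events = [events[i] for i in rng.permutation(len(events))]
        for ev in events:
            if ev == "d":
                absent = [i for i in range(n_areas) if not mask >> i & 1]
                if absent:
                    mask |= 1 << absent[int(rng.integers(len(absent)))]
            else:
                present = [i for i in range(n_areas) if mask >> i & 1]
                if len(present) > 1:  # an extinction never empties the range
                    mask &= ~(1 << present[int(rng.integers(len(present)))])
        return mask

    def walk(node, mask: int) -> None:
        truth[clades[id(node)]] = mask
        if node.is_leaf:
            tip_ranges[node.label] = mask
            return
        for child in node.children:
            walk(child, evolve(mask))

    walk(tree.root, alphabet.parse(params.root_range))
    return tip_ranges, truth
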