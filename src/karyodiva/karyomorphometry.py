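"""Karyotype statistics from multi-plate metaphase measurements.

The pipeline is: pair homologous chromosomes on each plate (minimum-cost
perfect matching on a dissimilarity combining relative length and
centromeric index), rank the pairs by decreasing mean length, identify
rank-k pairs across plates as haploid chromosome k, then average.  From
the averaged haploid complement we compute the classical descriptors:

* centromeric index CI = 100 * short / (short + long), arm ratio
  r = long / short, and the centromere-position classes of Levan
  (M, m, sm, st, t);
* total and mean haploid complement length (THCL, MCL), shortest and
  longest chromosome (S, L) and their ratio R = L / S;
* the asymmetry indices CV_CL (interchromosomal heterogeneity of
  length), CV_CI (heterogeneity of centromere position) and M_CA (mean
  centromeric asymmetry, mean of 100 * (long - short) / (long + short));
* the two-way Stebbins symmetry category (digit from the proportion of
  chromosomes with arm ratio >= 2, letter from R).

Coefficients of variation and standard errors use the sample (n-1)
standard deviation.  All values are kept at full precision; rounding to
two decimals happens only in the report writer.
"""

from __future__ import annotations

import json
import math
import statistics
from dataclasses import dataclass, asdict
from typing import Sequence

import networkx as nx

from .measurement_io import ChromosomeMeasurement, MeasurementTable, MeasurementError

__all__ = [
    "HaploidChromosome",
    "Karyotype",
    "KaryotypeSummary",
    "centromeric_index",
    "classify_levan",
    "pair_homologs",
    "aggregate_plates",
    "karyotype_formula",
    "asymmetry_indices",
    "stebbins_category",
    "summarize",
    "karyotype_to_json",
    "karyotype_from_json",
]

LEVAN_CLASSES = ("M", "m", "sm", "st", "t", "T")


def centromeric_index(short_arm: float, long_arm: float) -> float:
    """Centromeric index: short arm as a percentage of total length.

    Defined on oriented arms (0 < short <= long), hence in (0, 50].
    """
    if short_arm <= 0 or long_arm <= 0 or short_arm > long_arm:
        raise ValueError(
            f"need 0 < short_arm <= long_arm, got ({short_arm}, {long_arm})"
        )
    return 100.0 * short_arm / (short_arm + long_arm)


def classify_levan(arm_ratio: float) -> str:
    """Levan centromere-position class from the arm ratio r = long/short.

    M (median point) for r == 1 exactly; m (median region) for 1 < r < 1.7;
    sm for 1.7 <= r < 3; st for 3 <= r < 7; t for r >= 7.  Boundaries are
    inclusive on the less symmetric class.
    """
    if arm_ratio < 1:
        raise ValueError(f"arm ratio must be >= 1, got {arm_ratio}")
    if arm_ratio == 1:
        return "M"
    if arm_ratio < 1.7:
        return "m"
    if arm_ratio < 3.0:
        return "sm"
    if arm_ratio < 7.0:
        return "st"
    return "t"


# --- homolog pairing -------------------------------------------------------

# Costs are quantized to integers at this resolution so the matching runs
# on exact arithmetic (no float ties inside the solver).
_COST_QUANTUM = 1e-12
# Base of the positional tie-break encoding; must exceed N^2/2 for the
# largest plate handled (N chromosomes).
_TIEBREAK_BASE = 1 << 12


def _pair_dissimilarity(a: ChromosomeMeasurement, b: ChromosomeMeasurement,
                        mean_length: float,
                        weights: tuple[float, float]) -> float:
    w_len, w_ci = weights
    d_len = abs(a.total_length - b.total_length) / mean_length
    d_ci = abs(a.centromeric_index - b.centromeric_index) / 50.0
    return w_len * d_len + w_ci * d_ci


def pair_homologs(plate: Sequence[ChromosomeMeasurement],
                  weights: tuple[float, float] = (1.0, 1.0),
                  ) -> list[tuple[ChromosomeMeasurement, ChromosomeMeasurement]]:
    """Pair homologous chromosomes of one plate by length and centromeric index.

    Returns the perfect matching minimizing the summed dissimilarity
    d(i, j) = w_len * |CL_i - CL_j| / mean(CL) + w_ci * |CI_i - CI_j| / 50.
    The optimum is global (blossom algorithm on exact integer weights);
    among co-optimal matchings the lexicographically smallest pairing by
    sorted chromosome ids is returned.  Pairs are listed with the
    smaller-id member first, sorted by that id.
    """
    chroms = sorted(plate, key=lambda m: m.chromosome_id)
    n = len(chroms)
    if n == 0 or n % 2 != 0:
        raise MeasurementError(f"cannot pair an odd number of chromosomes ({n})")
    ids = [m.chromosome_id for m in chroms]
    if len(set(ids)) != n:
        raise MeasurementError("duplicate chromosome ids on plate")
    if len({m.plate_id for m in chroms}) != 1:
        raise MeasurementError("pair_homologs expects measurements from one plate")
    if n == 2:
        return [(chroms[0], chroms[1])]

    mean_length = sum(m.total_length for m in chroms) / n
    # Integer weight = quantized cost * SCALE + positional penalty.  The
    # penalty j * BASE^(n - i) for the edge (i, j), i < j in id order,
    # totals below SCALE, and orders matchings lexicographically: the
    # partner choice of the smallest unmatched id dominates all later
    # choices (BASE > n^2 / 2).
    scale = (n + 1) * _TIEBREAK_BASE ** (n + 1)
    G = nx.Graph()
    G.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            cost = _pair_dissimilarity(chroms[i], chroms[j], mean_length, weights)
            q = round(cost / _COST_QUANTUM)
            G.add_edge(i, j, weight=q * scale + j * _TIEBREAK_BASE ** (n - i))
    matching = nx.min_weight_matching(G)
    pairs = sorted(tuple(sorted(e)) for e in matching)
    return [(chroms[i], chroms[j]) for i, j in pairs]


# --- aggregation across plates --------------------------------------------

@dataclass(frozen=True)
class HaploidChromosome:
    """One averaged haploid chromosome, ranked by decreasing mean length."""

    rank: int
    mean_total_length: float
    se_total_length: float
    mean_short_arm: float
    mean_long_arm: float

    @property
    def centromeric_index(self) -> float:
        return centromeric_index(self.mean_short_arm, self.mean_long_arm)

    @property
    def arm_ratio(self) -> float:
        return self.mean_long_arm / self.mean_short_arm

    @property
    def levan_class(self) -> str:
        return classify_levan(self.arm_ratio)


@dataclass(frozen=True)
class Karyotype:
    """Ordered haploid complement averaged over metaphase plates."""

    diploid_number: int
    chromosomes: tuple[HaploidChromosome, ...]
    n_plates: int

    @property
    def n(self) -> int:
        return self.diploid_number // 2


@dataclass(frozen=True)
class KaryotypeSummary:
    """The comparative-table row set for one karyotype (full precision)."""

    diploid_number: int
    thcl: float
    thcl_se: float
    formula: str
    cv_cl: float
    cv_ci: float
    m_ca: float
    shortest: float
    shortest_se: float
    longest: float
    longest_se: float
    mcl: float
    mcl_se: float
    ratio_r: float
    stebbins: str


def _mean_se(values: Sequence[float]) -> tuple[float, float]:
    m = sum(values) / len(values)
    if len(values) == 1:
        return m, 0.0
    sd = statistics.stdev(values)
    return m, sd / math.sqrt(len(values))


def aggregate_plates(table: MeasurementTable,
                     weights: tuple[float, float] = (1.0, 1.0),
                     normalize: bool = False) -> Karyotype:
    """Average per-plate homolog pairs into a haploid karyotype.

    Each plate is paired with :func:`pair_homologs`; within a plate,
    pairs are ranked by decreasing pair-mean total length (ties by pair
    ids); rank-k pairs are identified across plates as haploid
    chromosome k.  With ``normalize=True`` arm lengths are divided by
    the plate's total complement length first (relative lengths), which
    absorbs condensation differences between plates.
    """
    table.validate()
    plates = table.plates()
    per_plate_ranked: list[list[tuple[float, float, float]]] = []
    for plate_id, chroms in sorted(plates.items()):
        factor = 1.0
        if normalize:
            factor = 1.0 / sum(m.total_length for m in chroms)
        pairs = pair_homologs(chroms, weights=weights)
        stats = []
        for a, b in pairs:
            short = factor * (a.short_arm + b.short_arm) / 2.0
            long = factor * (a.long_arm + b.long_arm) / 2.0
            key = tuple(sorted((a.chromosome_id, b.chromosome_id)))
            stats.append((short + long, short, long, key))
        stats.sort(key=lambda t: (-t[0], t[3]))
        per_plate_ranked.append([(t[0], t[1], t[2]) for t in stats])

    n = len(per_plate_ranked[0])
    n_plates = len(per_plate_ranked)
    chromosomes = []
    for k in range(n):
        totals = [plate[k][0] for plate in per_plate_ranked]
        shorts = [plate[k][1] for plate in per_plate_ranked]
        longs = [plate[k][2] for plate in per_plate_ranked]
        mean_total, se_total = _mean_se(totals)
        chromosomes.append(HaploidChromosome(
            rank=k + 1,
            mean_total_length=mean_total,
            se_total_length=se_total,
            mean_short_arm=sum(shorts) / n_plates,
            mean_long_arm=sum(longs) / n_plates,
        ))
    return Karyotype(diploid_number=2 * n, chromosomes=tuple(chromosomes),
                     n_plates=n_plates)


# --- complement-level statistics ------------------------------------------

def karyotype_formula(karyotype: Karyotype) -> str:
    """Haploid tally per Levan class, e.g. ``"9m + 7sm"``.

    M is merged into m and T into t; classes appear in the order m, sm,
    st, t with zero counts omitted.
    """
    if not karyotype.chromosomes:
        raise ValueError("empty karyotype")
    merged = {"M": "m", "T": "t"}
    counts = {"m": 0, "sm": 0, "st": 0, "t": 0}
    for chrom in karyotype.chromosomes:
        cls = chrom.levan_class
        counts[merged.get(cls, cls)] += 1
    parts = [f"{count}{cls}" for cls, count in counts.items() if count]
    return " + ".join(parts)


def asymmetry_indices(karyotype: Karyotype) -> dict[str, float]:
    """Complement-level length/asymmetry statistics over the n haploid chromosomes.

    Requires n >= 2 for the coefficients of variation.
    """
    chroms = karyotype.chromosomes
    if len(chroms) < 2:
        raise ValueError("coefficients of variation need at least 2 chromosomes")
    lengths = [c.mean_total_length for c in chroms]
    cis = [c.centromeric_index for c in chroms]
    mca_terms = [
        100.0 * (c.mean_long_arm - c.mean_short_arm)
        / (c.mean_long_arm + c.mean_short_arm)
        for c in chroms
    ]
    thcl = sum(lengths)
    return {
        "cv_cl": 100.0 * statistics.stdev(lengths) / statistics.mean(lengths),
        "cv_ci": 100.0 * statistics.stdev(cis) / statistics.mean(cis),
        "m_ca": statistics.mean(mca_terms),
        "thcl": thcl,
        "mcl": thcl / len(chroms),
        "shortest": min(lengths),
        "longest": max(lengths),
        "ratio_r": max(lengths) / min(lengths),
    }


def stebbins_category(karyotype: Karyotype) -> str:
    """Two-way Stebbins symmetry category, digit + letter (e.g. ``"2B"``).

    Letter from R = longest/shortest: A if R < 2, B if 2 <= R <= 4, C if
    R > 4.  Digit from the proportion p of haploid chromosomes with arm
    ratio >= 2: 1 if p = 0, 2 if 0 < p <= 0.5, 3 if 0.5 < p < 1, 4 if
    p = 1.  Computed on the averaged haploid chromosomes.
    """
    chroms = karyotype.chromosomes
    if not chroms:
        raise ValueError("empty karyotype")
    lengths = [c.mean_total_length for c in chroms]
    ratio_r = max(lengths) / min(lengths)
    letter = "A" if ratio_r < 2 else ("B" if ratio_r <= 4 else "C")
    p = sum(1 for c in chroms if c.arm_ratio >= 2) / len(chroms)
    if p == 0:
        digit = "1"
    elif p <= 0.5:
        digit = "2"
    elif p < 1:
        digit = "3"
    else:
        digit = "4"
    return digit + letter


def summarize(karyotype: Karyotype) -> KaryotypeSummary:
    """Assemble the full comparative-table summary at full precision."""
    idx = asymmetry_indices(karyotype)
    chroms = karyotype.chromosomes
    shortest = min(chroms, key=lambda c: c.mean_total_length)
    longest = max(chroms, key=lambda c: c.mean_total_length)
    # SE of THCL: plate-level totals are sums of independent per-rank means,
    # approximated by summing variances of the rank means.
    thcl_se = math.sqrt(sum(c.se_total_length ** 2 for c in chroms))
    return KaryotypeSummary(
        diploid_number=karyotype.diploid_number,
        thcl=idx["thcl"],
        thcl_se=thcl_se,
        formula=karyotype_formula(karyotype),
        cv_cl=idx["cv_cl"],
        cv_ci=idx["cv_ci"],
        m_ca=idx["m_ca"],
        shortest=shortest.mean_total_length,
        shortest_se=shortest.se_total_length,
        longest=longest.mean_total_length,
        longest_se=longest.se_total_length,
        mcl=idx["mcl"],
        mcl_se=thcl_se / len(chroms),
        ratio_r=idx["ratio_r"],
        stebbins=stebbins_category(karyotype),
    )


# --- serialization ---------------------------------------------------------

def karyotype_to_json(karyotype: Karyotype) -> str:
    payload = {
        "diploid_number": karyotype.diploid_number,
        "n_plates": karyotype.n_plates,
        "chromosomes": [asdict(c) for c in karyotype.chromosomes],
    }
    return json.dumps(payload, indent=2, sort_keys=True)


def karyotype_from_json(text: str) -> Karyotype:
    payload = json.loads(text)
    chroms = tuple(HaploidChromosome(**c) for c in payload["chromosomes"])
    return Karyotype(diploid_number=payload["diploid_number"],
                     chromosomes=chroms, n_plates=payload["n_plates"])
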