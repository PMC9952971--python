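import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from karyodiva import (
    ChromosomeMeasurement,
    HaploidChromosome,
    Karyotype,
    aggregate_plates,
    asymmetry_indices,
    centromeric_index,
    classify_levan,
    karyotype_formula,
    pair_homologs,
    stebbins_category,
    summarize,
)
from karyodiva.karyomorphometry import karyotype_from_json, karyotype_to_json
from karyodiva import synthetic_data as sd
from karyodiva.measurement_io import MeasurementError

from oracles import brute_force_pairing


def _chrom(plate, cid, short, long):
    return ChromosomeMeasurement(plate, cid, short, long)


def _karyotype(arm_pairs):
    """Karyotype from (short, long) tuples, ranked by decreasing length."""
    ordered = sorted(arm_pairs, key=lambda a: -(a[0] + a[1]))
    chroms = tuple(
        HaploidChromosome(rank=i + 1, mean_total_length=s + l,
                          se_total_length=0.0, mean_short_arm=s,
                          mean_long_arm=l)
        for i, (s, l) in enumerate(ordered)
    )
    return Karyotype(diploid_number=2 * len(chroms), chromosomes=chroms,
                     n_plates=1)


# --- centromeric index and Levan classes ----------------------------------

@pytest.mark.parametrize("short,long,expected", [
    (1.0, 1.0, 50.0),
    (0.5, 1.5, 25.0),
    (0.9, 2.1, 30.0),
])
def test_centromeric_index_formula(short, long, expected):
    assert centromeric_index(short, long) == pytest.approx(expected)


@pytest.mark.parametrize("short,long", [(0.0, 1.0), (-1.0, 1.0), (2.0, 1.0)])
def test_centromeric_index_domain(short, long):
    with pytest.raises(ValueError):
        centromeric_index(short, long)


@pytest.mark.parametrize("ratio,expected", [
    (1.0, "M"), (1.5, "m"), (1.6999, "m"), (1.7, "sm"), (2.0, "sm"),
    (2.9999, "sm"), (3.0, "st"), (6.9, "st"), (7.0, "t"), (12.0, "t"),
])
def test_levan_bands_lower_inclusive(ratio, expected):
    assert classify_levan(ratio) == expected


def test_levan_rejects_ratio_below_one():
    with pytest.raises(ValueError):
        classify_levan(0.9)


# --- homolog pairing -------------------------------------------------------

def test_pairing_unique_zero_cost_matching():
    plate = [
        _chrom("P1", "c1", 1.4, 1.6), _chrom("P1", "c2", 0.7, 0.8),
        _chrom("P1", "c3", 1.4, 1.6), _chrom("P1", "c4", 0.7, 0.8),
    ]
    pairs = pair_homologs(plate)
    ids = [(a.chromosome_id, b.chromosome_id) for a, b in pairs]
    assert ids == [("c1", "c3"), ("c2", "c4")]


def test_pairing_two_chromosomes_is_trivial():
    plate = [_chrom("P1", "a", 1.0, 2.0), _chrom("P1", "b", 0.5, 0.7)]
    assert len(pair_homologs(plate)) == 1


@pytest.mark.parametrize("bad,exc", [
    ([_chrom("P1", "a", 1, 2)], MeasurementError),
    ([_chrom("P1", "a", 1, 2), _chrom("P1", "a", 1, 2)], MeasurementError),
    ([_chrom("P1", "a", 1, 2), _chrom("P2", "b", 1, 2)], MeasurementError),
])
def test_pairing_input_validation(bad, exc):
    with pytest.raises(exc):
        pair_homologs(bad)


def _random_plate(rng, n_chroms):
    chroms = []
    for i in range(n_chroms):
        long = float(rng.uniform(0.8, 3.0))
        short = float(rng.uniform(0.2, 1.0)) * long
        chroms.append(_chrom("P1", f"c{i:02d}", short, long))
    return chroms


def test_pairing_matches_exhaustive_oracle_small_plates():
    """Global optimality + lexicographic tie-break vs brute enumeration."""
    rng = np.random.default_rng(42)
    for trial in range(200):
        n = int(rng.choice([4, 6, 8, 10]))
        # occasionally quantize lengths to force cost ties
        plate = _random_plate(rng, n)
        if trial % 4 == 0:
            plate = [_chrom(c.plate_id, c.chromosome_id,
                            round(c.short_arm, 1), round(c.long_arm, 1))
                     for c in plate]
        _, oracle_pairs = brute_force_pairing(plate)
        got = [tuple(sorted((a.chromosome_id, b.chromosome_id)))
               for a, b in pair_homologs(plate)]
        assert got == oracle_pairs


# --- aggregation -----------------------------------------------------------

def test_noiseless_single_plate_recovers_truth_exactly():
    truth = sd.TrueKaryotype(arms=((1.5, 2.5), (0.8, 1.2)))
    table = sd.simulate_measurements(truth, n_plates=1, noise_sigma=0.0,
                                     plate_scale_sigma=0.0, seed=0)
    karyotype = aggregate_plates(table)
    assert karyotype.diploid_number == 4
    assert [c.mean_total_length for c in karyotype.chromosomes] == [4.0, 2.0]
    assert all(c.se_total_length == 0.0 for c in karyotype.chromosomes)


def test_vanishing_noise_limit_recovers_truth():
    truth = sd.condapanna_like_truth()
    table = sd.simulate_measurements(truth, n_plates=10, noise_sigma=1e-12,
                                     plate_scale_sigma=0.0, seed=3)
    karyotype = aggregate_plates(table)
    expected = sorted(truth.total_lengths, reverse=True)
    for chrom, true_len in zip(karyotype.chromosomes, expected):
        assert chrom.mean_total_length == pytest.approx(true_len, rel=1e-9)


def test_mean_lengths_within_three_se_of_truth(measurement_recovery_study):
    ok = measurement_recovery_study["means_within_3se"]
    assert sum(ok) / len(ok) >= 0.95


def test_cv_and_mca_recovered_within_15pct(measurement_recovery_study):
    ok = measurement_recovery_study["cv_within_15pct"]
    assert sum(ok) / len(ok) >= 0.90


# --- formula, indices, Stebbins -------------------------------------------

def test_formula_counts_and_order():
    all_m = _karyotype([(1.0, 1.3)] * 15)
    assert karyotype_formula(all_m) == "15m"
    mixed = _karyotype([(1.0, 1.3)] * 9 + [(0.5, 1.1)] * 7)
    assert karyotype_formula(mixed) == "9m + 7sm"
    one_sm = _karyotype([(0.5, 1.1)])
    assert karyotype_formula(one_sm) == "1sm"
    # M merges into m, T into t
    merged = _karyotype([(1.0, 1.0), (1.0, 1.2), (0.1, 1.0)])
    assert karyotype_formula(merged) == "2m + 1t"


def test_asymmetry_indices_hand_arithmetic():
    k = _karyotype([(1.0, 1.0), (2.0, 2.0)])  # lengths 2 and 4, CIs 50
    idx = asymmetry_indices(k)
    assert idx["cv_cl"] == pytest.approx(100 * math.sqrt(2) / 3, abs=0.005)
    assert round(idx["cv_cl"], 2) == 47.14
    assert idx["cv_ci"] == 0.0
    assert idx["m_ca"] == 0.0
    assert idx["thcl"] == 6.0 and idx["mcl"] == 3.0 and idx["ratio_r"] == 2.0


def test_mean_centromeric_asymmetry_mixed_arms():
    k = _karyotype([(1.0, 1.0), (1.0, 3.0)])
    assert asymmetry_indices(k)["m_ca"] == pytest.approx(25.0)


def test_cv_requires_two_chromosomes():
    k = _karyotype([(1.0, 1.0)])
    with pytest.raises(ValueError):
        asymmetry_indices(k)
    with pytest.raises(ValueError):
        summarize(k)


@pytest.mark.parametrize("arms,expected", [
    # R = 2.03, all arm ratios < 1.7 -> digit 1, letter B
    ([(1.48 / 2.3, 1.48 * 1.3 / 2.3)] + [(1.0, 1.3)] +
     [(3.005 / 2.3, 3.005 * 1.3 / 2.3)], "1B"),
    # R = 1.5, every ratio >= 2 -> 4A
    ([(1.0, 2.0), (1.5, 3.0)], "4A"),
    # R = 5, 3 of 5 ratios >= 2 -> 3C
    ([(0.5, 1.5), (1.0, 2.2), (1.2, 2.6), (2.0, 3.0), (4.0, 6.0)], "3C"),
])
def test_stebbins_category_rule(arms, expected):
    assert stebbins_category(_karyotype(arms)) == expected


def test_summary_reports_r_to_two_decimals(condapanna_noiseless_karyotype):
    summary = summarize(condapanna_noiseless_karyotype)
    assert round(summary.ratio_r, 2) == 2.03
    assert summary.formula == "15m"
    assert summary.diploid_number == 30


# --- invariants ------------------------------------------------------------

@settings(max_examples=50, deadline=None, derandomize=True)
@given(scale=st.floats(min_value=0.05, max_value=50.0),
       seed=st.integers(min_value=0, max_value=10_000))
def test_scale_invariance_of_dimensionless_statistics(scale, seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 9))
    arms = []
    for _ in range(n):
        long = float(rng.uniform(0.5, 3.0))
        short = float(rng.uniform(0.2, 1.0)) * long
        arms.append((short, long))
    base = _karyotype(arms)
    scaled = _karyotype([(s * scale, l * scale) for s, l in arms])
    i1, i2 = asymmetry_indices(base), asymmetry_indices(scaled)
    for key in ("cv_cl", "cv_ci", "m_ca", "ratio_r"):
        assert i2[key] == pytest.approx(i1[key], rel=1e-9)
    for key in ("thcl", "mcl", "shortest", "longest"):
        assert i2[key] == pytest.approx(i1[key] * scale, rel=1e-9)
    assert stebbins_category(base) == stebbins_category(scaled)
    assert karyotype_formula(base) == karyotype_formula(scaled)
    assert [c.levan_class for c in base.chromosomes] == \
        [c.levan_class for c in scaled.chromosomes]


def test_mca_zero_iff_all_arms_equal_and_monotone():
    equal = _karyotype([(1.0, 1.0), (2.0, 2.0), (0.5, 0.5)])
    assert asymmetry_indices(equal)["m_ca"] == 0.0
    # moving one CI away from 50 at fixed length strictly increases M_CA
    previous = 0.0
    for short in (0.95, 0.85, 0.7, 0.5):
        k = _karyotype([(short, 2.0 - short), (2.0, 2.0), (0.5, 0.5)])
        current = asymmetry_indices(k)["m_ca"]
        assert current > previous
        previous = current


def test_cv_cl_zero_iff_equal_lengths_and_r_at_least_one():
    equal_lengths = _karyotype([(0.8, 1.2), (0.5, 1.5), (1.0, 1.0)])
    idx = asymmetry_indices(equal_lengths)
    assert idx["cv_cl"] == pytest.approx(0.0, abs=1e-12)
    assert idx["ratio_r"] == pytest.approx(1.0)
    unequal = _karyotype([(0.8, 1.2), (0.5, 1.1)])
    assert asymmetry_indices(unequal)["cv_cl"] > 0
    assert asymmetry_indices(unequal)["ratio_r"] >= 1


def test_karyotype_json_round_trip(nicobarica_noiseless_karyotype):
    text = karyotype_to_json(nicobarica_noiseless_karyotype)
    assert karyotype_from_json(text) == nicobarica_noiseless_karyotype
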