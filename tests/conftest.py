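import pytest

from karyodiva import (
    AreaAlphabet,
    aggregate_plates,
    sdiva_support,
    summarize,
)
from karyodiva import synthetic_data as sd


@pytest.fixture(scope="session")
def abcd():
    return AreaAlphabet("ABCD")


@pytest.fixture(scope="session")
def condapanna_noiseless_karyotype():
    table = sd.simulate_measurements(sd.condapanna_like_truth(), n_plates=1,
                                     noise_sigma=0.0, plate_scale_sigma=0.0,
                                     seed=0)
    return aggregate_plates(table)


@pytest.fixture(scope="session")
def nicobarica_noiseless_karyotype():
    table = sd.simulate_measurements(sd.nicobarica_like_truth(), n_plates=1,
                                     noise_sigma=0.0, plate_scale_sigma=0.0,
                                     seed=0)
    return aggregate_plates(table)


@pytest.fixture(scope="session")
def measurement_recovery_study():
    """200 seeded replicates of the full measurement->karyotype pipeline.

    Study conditions: 15-pair truth complement, 10 plates, 3% relative
    arm noise, 5% per-plate condensation spread.  Returns per-replicate
    success indicators for (a) CV_CL/CV_CI/M_CA within +-15% relative
    error of the generator truth and (b) every mean chromosome length
    within 3 standard errors of its true value.
    """
    truth = sd.condapanna_like_truth()
    ref = summarize(aggregate_plates(sd.simulate_measurements(
        truth, n_plates=1, noise_sigma=0.0, plate_scale_sigma=0.0, seed=0)))
    true_vals = {"cv_cl": ref.cv_cl, "cv_ci": ref.cv_ci, "m_ca": ref.m_ca}
    true_lengths = sorted(truth.total_lengths, reverse=True)

    cv_ok, se_ok = [], []
    for seed in range(200):
        table = sd.simulate_measurements(truth, n_plates=10, noise_sigma=0.03,
                                         plate_scale_sigma=0.05, seed=seed)
        karyotype = aggregate_plates(table)
        summary = summarize(karyotype)
        cv_ok.append(all(
            abs(getattr(summary, name) - value) / value <= 0.15
            for name, value in true_vals.items()
        ))
        se_ok.append(all(
            abs(c.mean_total_length - true_lengths[i]) <= 3 * c.se_total_length
            for i, c in enumerate(karyotype.chromosomes)
        ))
    return {"cv_within_15pct": cv_ok, "means_within_3se": se_ok}


@pytest.fixture(scope="session")
def sdiva_root_recovery_study(abcd):
    """100 seeded replicates of tree + range simulation and S-DIVA.

    Yule trees of 8 tips, dispersal = extinction = 0.05 events per
    branch, root range A.  Records whether the true root range is among
    the top two supported ranges at the root.
    """
    hits = []
    for seed in range(100):
        tree = sd.simulate_yule_tree(8, seed=1000 + seed)
        params = sd.RangeSimParams(dispersal_rate=0.05, extinction_rate=0.05,
                                   alphabet=abcd, root_range="A",
                                   seed=2000 + seed)
        tips, truth = sd.simulate_range_evolution(tree, params)
        support = sdiva_support(tree, [tree], tips, abcd)
        root_clade = frozenset(tree.tips())
        freqs = support.supports[root_clade].frequencies
        top2 = [r for r, _ in sorted(freqs.items(),
                                     key=lambda kv: (-kv[1], kv[0]))[:2]]
        hits.append(abcd.format(truth[root_clade]) in top2)
    return hits
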