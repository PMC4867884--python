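"""Classical HMM recursions against closed forms and exhaustive enumeration."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chisquare

import ksegment as ks
from conftest import random_gaussian_model, random_instance


def test_single_state_marginals_are_one():
    m = ks.HMMParams(1, [1.0], [[1.0]], "gaussian",
                     {"means": [0.0], "variances": [1.0]})
    fb = ks.forward_backward(m, np.array([0.3, -1.2, 4.0]))
    assert np.array_equal(fb.posterior_marginals(), np.ones((3, 1)))
    path, _ = ks.viterbi(m, np.array([0.3, -1.2, 4.0]))
    assert np.array_equal(path, [1, 1, 1])


def test_state_symmetric_model_gives_uniform_marginals():
    # identical emissions and a symmetric chain carry no state information
    m = ks.HMMParams(2, [0.5, 0.5], [[0.5, 0.5], [0.5, 0.5]], "gaussian",
                     {"means": [1.0, 1.0], "variances": [2.0, 2.0]})
    fb = ks.forward_backward(m, np.array([0.1, 0.2, 0.3]))
    assert np.allclose(fb.posterior_marginals(), 0.5)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_forward_evidence_matches_enumeration(seed):
    model, y = random_instance(seed, M=3, N=8)
    fb = ks.forward_backward(model, y)
    en = ks.enumerate_posterior(model, y)
    assert fb.log_evidence == pytest.approx(en.log_evidence, abs=1e-10)
    # marginals agree with the enumerated site posteriors
    site, _ = en.marginals_under_event(None)
    assert np.allclose(fb.posterior_marginals(), site, atol=1e-10)


def test_forward_backward_evidence_consistent_at_every_position():
    from scipy.special import logsumexp

    model, y = random_instance(7, M=3, N=30)
    fb = ks.forward_backward(model, y)
    per_n = logsumexp(fb.log_alpha + fb.log_beta, axis=1)
    assert np.allclose(per_n, fb.log_evidence, atol=1e-8)


@pytest.mark.parametrize("seed", [3, 4])
def test_viterbi_matches_enumeration(seed):
    model, y = random_instance(seed, M=2, N=10)
    path, score = ks.viterbi(model, y)
    epath, escore = ks.enumerate_posterior(model, y).map_under_event(None)
    assert score == pytest.approx(escore, abs=1e-10)
    assert np.array_equal(path, epath)
    assert score == pytest.approx(ks.path_log_joint(model, y, path), abs=1e-10)


def test_viterbi_nearest_mean_labelling_in_informative_limit():
    m = ks.HMMParams(2, [0.5, 0.5], [[0.5, 0.5], [0.5, 0.5]], "gaussian",
                     {"means": [-3.0, 3.0], "variances": [1e-6, 1e-6]})
    y = np.array([-3.0, 3.0, 3.0, -3.0])
    path, _ = ks.viterbi(m, y)
    assert np.array_equal(path, [1, 2, 2, 1])


def test_degenerate_evidence_raises():
    m = ks.HMMParams(2, [1.0, 0.0], [[1.0, 0.0], [0.0, 1.0]], "categorical",
                     {"probs": [[1.0, 0.0], [0.0, 1.0]]})
    with pytest.raises(ks.DegenerateEvidenceError):
        ks.forward_backward(m, np.array([2, 2]))  # symbol 2 impossible from state 1
    with pytest.raises(ks.DegenerateEvidenceError):
        ks.viterbi(m, np.array([2, 2]))


def test_ffbs_deterministic_model_gives_constant_paths():
    m = ks.HMMParams(2, [0.0, 1.0], [[1.0, 0.0], [0.0, 1.0]], "gaussian",
                     {"means": [0.0, 0.0], "variances": [1.0, 1.0]})
    draws = ks.ffbs_sample(m, np.zeros(6), n_samples=20, seed=0)
    assert np.all(draws == 2)


def test_ffbs_matches_enumerated_posterior(tiny_enumerable):
    model, y, en = tiny_enumerable
    draws = ks.ffbs_sample(model, y, n_samples=50_000, seed=11)
    probs = en.path_probabilities(None)
    keys = list(probs)
    index = {k: i for i, k in enumerate(keys)}
    observed = np.zeros(len(keys))
    for p in draws:
        observed[index[tuple(p)]] += 1
    expected = np.array([probs[k] for k in keys]) * draws.shape[0]
    res = chisquare(observed, expected)
    assert res.pvalue > 0.001


def test_ffbs_seed_contract(tiny_enumerable):
    model, y, _ = tiny_enumerable
    a = ks.ffbs_sample(model, y, 10, seed=5)
    b = ks.ffbs_sample(model, y, 10, seed=5)
    c = ks.ffbs_sample(model, y, 10, seed=6)
    assert np.array_equal(a, b)
    assert not np.array_equal(a, c)
    with pytest.raises(ks.InputError):
        ks.ffbs_sample(model, y, 0, seed=1)


def test_best_list_matches_enumeration():
    model, y = random_instance(9, M=2, N=6)
    en = ks.enumerate_posterior(model, y)
    got = ks.best_list_viterbi(model, y, 10)
    expected = en.top_paths(10)
    scores = [s for _, s in got]
    assert np.all(np.diff(scores) <= 1e-12)  # nonincreasing
    for (p, s), (ep, es) in zip(got, expected):
        assert s == pytest.approx(es, abs=1e-9)
    vp, vs = ks.viterbi(model, y)
    assert np.array_equal(got[0][0], vp) and got[0][1] == pytest.approx(vs)
    # paths are distinct
    assert len({tuple(p) for p, _ in got}) == 10


def test_best_list_p_exceeding_path_count_warns_and_returns_all():
    model, y = random_instance(10, M=2, N=3)
    with pytest.warns(UserWarning):
        got = ks.best_list_viterbi(model, y, 100)
    assert len(got) == 8


def test_em_single_state_recovers_sample_moments():
    rng = np.random.default_rng(2)
    y = rng.normal(1.5, 2.0, size=400)
    init = ks.HMMParams(1, [1.0], [[1.0]], "gaussian",
                        {"means": [0.0], "variances": [1.0]})
    fit, trace = ks.em_fit(init, y, max_iter=50)
    assert fit.emission_params["means"][0] == pytest.approx(y.mean(), abs=1e-8)
    assert fit.emission_params["variances"][0] == pytest.approx(y.var(), rel=1e-6)
    assert np.all(np.diff(trace) > -1e-8)


def test_em_never_decreases_from_any_init():
    rng = np.random.default_rng(3)
    y = np.concatenate([rng.normal(-2, 1, 50), rng.normal(2, 1, 50)])
    for seed in range(3):
        init = random_gaussian_model(np.random.default_rng(seed), 2)
        _, trace = ks.em_fit(init, y, max_iter=15)
        assert np.all(np.diff(trace) > -1e-8)


def test_em_recovers_benchmark_means_over_replicates():
    """Informative-init EM on the 3-state benchmark recovers the generative
    means within 0.2 on 20 seeded replicates, allowing for the occasional
    EM local optimum (observed on ~1 in 20 replicates)."""
    design = ks.SimulationDesign()
    true_means = np.asarray(design.means)
    errors = []
    for seed in range(1, 21):
        _, y = ks.simulate_hmm(design, seed)
        fit, trace = ks.em_fit(ks.informative_init(y), y)
        est = np.sort(fit.emission_params["means"])
        errors.append(np.abs(est - true_means).max())
        assert np.all(np.diff(trace) > -1e-8)
    assert sum(e < 0.2 for e in errors) >= 19
    assert np.median(errors) < 0.2


def test_model_json_roundtrip_is_bit_exact():
    model = random_gaussian_model(np.random.default_rng(0), 3)
    back = ks.HMMParams.from_json(model.to_json())
    assert np.array_equal(back.pi0, model.pi0)
    assert np.array_equal(back.A, model.A)
    assert np.array_equal(back.emission_params["means"], model.emission_params["means"])
    assert np.array_equal(
        back.emission_params["variances"], model.emission_params["variances"]
    )
    cat = ks.HMMParams(2, [0.4, 0.6], [[0.9, 0.1], [0.2, 0.8]], "categorical",
                       {"probs": [[0.3, 0.7], [0.5, 0.5]]})
    assert np.array_equal(
        ks.HMMParams.from_json(cat.to_json()).emission_params["probs"],
        cat.emission_params["probs"],
    )


@pytest.mark.parametrize(
    "kwargs, fragment",
    [
        (dict(pi0=[0.5, 0.4]), "pi0"),
        (dict(A=[[0.5, 0.4], [0.5, 0.5]]), "row 1"),
        (dict(emission_params={"means": [0.0, 0.0], "variances": [1.0, -1.0]}),
         "variances"),
    ],
)
def test_validation_errors_name_the_offender(kwargs, fragment):
    base = dict(
        M=2, pi0=[0.5, 0.5], A=[[0.5, 0.5], [0.5, 0.5]],
        emission_family="gaussian",
        emission_params={"means": [0.0, 1.0], "variances": [1.0, 1.0]},
    )
    base.update(kwargs)
    with pytest.raises(ks.InputError, match=fragment):
        ks.HMMParams(**base)


def test_observation_type_mismatch_is_an_input_error():
    cat = ks.HMMParams(2, [0.5, 0.5], [[0.5, 0.5], [0.5, 0.5]], "categorical",
                       {"probs": [[0.5, 0.5], [0.5, 0.5]]})
    with pytest.raises(ks.InputError):
        ks.forward_backward(cat, np.array([1.5, 2.0]))
    with pytest.raises(ks.InputError):
        ks.forward_backward(cat, np.array([0, 1]))  # symbols are 1-based


@settings(deadline=None, max_examples=50)
@given(st.lists(st.integers(1, 4), min_size=1, max_size=40))
def test_segmentation_roundtrips_and_counts_runs(states):
    x = np.array(states)
    seg = ks.Segmentation.from_path(x)
    assert np.array_equal(seg.to_path(), x)
    assert len(seg) == ks.count_segments(x)
    # segments tile 1..N, adjacent states differ
    assert seg.segments[0][0] == 1 and seg.segments[-1][1] == x.size
    for (s1, e1, m1), (s2, e2, m2) in zip(seg.segments, seg.segments[1:]):
        assert s2 == e1 + 1 and m1 != m2


def test_segmentation_bed_coordinates():
    seg = ks.Segmentation(segments=[(1, 3, 2), (4, 5, 1)], N=5)
    assert seg.to_bed("chr1") == [("chr1", 0, 3, 2), ("chr1", 3, 5, 1)]
    assert ks.Segmentation.from_bed(seg.to_bed()).segments == seg.segments
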