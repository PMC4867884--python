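"""k-segment decoding, count posteriors, constrained sampling and marginals."""

import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import chisquare

import ksegment as ks
from ksegment import _dp
from ksegment.counting import build_augmented_transition
from conftest import random_instance

SPECS = {
    "standard": ks.CountingSpec(),
    "generalized": ks.CountingSpec(
        variant="generalized", mu=[0, 1, 0], C=[[0, 1, 0], [0, 0, 0], [0, 1, 0]]
    ),
    "excursion": ks.CountingSpec(variant="excursion", null_states={1}),
    "restricted_excursion": ks.CountingSpec(
        variant="restricted_excursion", null_states={1}
    ),
}


def uniform_two_state(N):
    model = ks.HMMParams(
        2, [0.5, 0.5], [[0.5, 0.5], [0.5, 0.5]], "gaussian",
        {"means": [0.0, 0.0], "variances": [1.0, 1.0]},
    )
    return model, np.zeros(N)


def test_uniform_model_count_posterior_closed_form():
    # 8 equiprobable paths: 2 constant, 4 with two segments, 2 alternating
    model, y = uniform_two_state(3)
    dist = ks.kseg_forward(model, y, ks.CountingSpec(), k_max=3)
    assert dist.probs == pytest.approx([0.25, 0.5, 0.25], abs=1e-12)
    assert dist.tail == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("variant", list(SPECS), ids=list(SPECS))
def test_count_posterior_matches_enumeration(variant):
    spec = SPECS[variant]
    model, y = random_instance(31, M=3, N=8)
    en = ks.enumerate_posterior(model, y, spec)
    dist = ks.kseg_forward(model, y, spec, k_max=8)
    probs, tail = en.count_distribution(8)
    assert np.allclose(dist.probs, probs[dist.k_min :], atol=1e-10)
    assert dist.tail == pytest.approx(tail, abs=1e-10)
    assert dist.total() == pytest.approx(1.0, abs=1e-10)


@pytest.mark.parametrize("variant", list(SPECS), ids=list(SPECS))
@pytest.mark.parametrize(
    "event",
    [
        ks.SegmentEvent.exactly(2),
        ks.SegmentEvent.at_most(3),
        ks.SegmentEvent.greater_than(2),
        ks.SegmentEvent.between(2, 4),
    ],
    ids=str,
)
def test_event_constrained_map_matches_enumeration(variant, event):
    spec = SPECS[variant]
    model, y = random_instance(32, M=3, N=7)
    en = ks.enumerate_posterior(model, y, spec)
    epath, escore = en.map_under_event(event)
    if epath is None:
        with pytest.raises(ks.InfeasibleEventError):
            ks.kseg_viterbi(model, y, spec, event)
        return
    path, score = ks.kseg_viterbi(model, y, spec, event)
    assert score == pytest.approx(escore, abs=1e-10)
    assert event.matches(ks.count_for_spec(path, spec, M=3))
    assert score == pytest.approx(ks.path_log_joint(model, y, path), abs=1e-10)


def test_single_segment_map_is_best_constant_path():
    model, y = random_instance(33, M=3, N=9)
    path, score = ks.kseg_viterbi(model, y, ks.CountingSpec(), ks.SegmentEvent.exactly(1))
    candidates = [
        ks.path_log_joint(model, y, np.full(9, m + 1)) for m in range(3)
    ]
    assert len(set(path)) == 1
    assert score == pytest.approx(max(candidates), abs=1e-12)


def test_n_segment_map_is_alternating_and_errors_without_offdiagonals():
    model, y = random_instance(34, M=2, N=6)
    path, _ = ks.kseg_viterbi(model, y, ks.CountingSpec(), ks.SegmentEvent.exactly(6))
    assert np.all(path[:-1] != path[1:])
    frozen = ks.HMMParams(
        2, [0.5, 0.5], np.eye(2), "gaussian",
        {"means": [0.0, 1.0], "variances": [1.0, 1.0]},
    )
    with pytest.raises(ks.InfeasibleEventError):
        ks.kseg_viterbi(frozen, y, ks.CountingSpec(), ks.SegmentEvent.exactly(6))


def test_infeasible_events_raise_not_fall_back():
    model, y = random_instance(35, M=2, N=5)
    with pytest.raises(ks.InfeasibleEventError):
        ks.kseg_viterbi(model, y, ks.CountingSpec(), ks.SegmentEvent.greater_than(5))
    with pytest.raises(ks.InfeasibleEventError):
        ks.kseg_viterbi(model, y, ks.CountingSpec(), ks.SegmentEvent.exactly(0))
    # zero counts are allowed exactly when the variant can start at zero
    path, _ = ks.kseg_viterbi(model, y, SPECS["excursion"].bind(2),
                              ks.SegmentEvent.exactly(0))
    assert ks.count_excursions(path, SPECS["excursion"])[0] == 0


def test_summary_entries_match_enumeration_and_contain_viterbi():
    model, y = random_instance(36, M=2, N=8)
    en = ks.enumerate_posterior(model, y)
    summ = ks.kseg_summary(model, y, ks.CountingSpec(), k_max=5)
    for k, path, score in summ.entries():
        epath, escore = en.map_under_event(ks.SegmentEvent.exactly(k))
        assert score == pytest.approx(escore, abs=1e-10)
        if path is not None:
            assert ks.count_segments(path) == k
            # entry scores are the scores of their own paths
            assert score == pytest.approx(ks.path_log_joint(model, y, path), abs=1e-10)
    _, ab_score = en.map_under_event(ks.SegmentEvent.greater_than(5))
    assert summ.absorbing_score == pytest.approx(ab_score, abs=1e-10)
    vpath, _ = ks.viterbi(model, y)
    assert any(np.array_equal(vpath, p) for p in summ.all_paths())


def test_summary_scores_never_beat_viterbi_with_equality_at_its_count():
    model, y = random_instance(37, M=3, N=8)
    vpath, vscore = ks.viterbi(model, y)
    vcount = ks.count_segments(vpath)
    summ = ks.kseg_summary(model, y, ks.CountingSpec(), k_max=8)
    for k, _, score in summ.entries():
        assert score <= vscore + 1e-12
    assert summ.scores[vcount] == pytest.approx(vscore, abs=1e-12)


def test_consecutive_summary_paths_can_be_non_nested():
    """The k+1-segment MAP need not split one segment of the k-segment MAP;
    some instance in a small random family exhibits a boundary move."""

    def nested(coarse, fine):
        cb = {(s, e) for s, e, _ in ks.Segmentation.from_path(coarse).segments}
        fb = {(s, e) for s, e, _ in ks.Segmentation.from_path(fine).segments}
        # nested split: all but one coarse segment survive intact
        return len(cb - fb) <= 1

    found = False
    for seed in range(40):
        model, y = random_instance(seed, M=3, N=12)
        summ = ks.kseg_summary(model, y, ks.CountingSpec(), k_max=6)
        for k in range(1, 6):
            a, b = summ.paths.get(k), summ.paths.get(k + 1)
            if a is not None and b is not None and not nested(a, b):
                found = True
    assert found


def test_mixture_decomposition_recovers_evidence_without_absorption():
    model, y = random_instance(38, M=3, N=40)
    logz = ks.forward_backward(model, y).log_evidence
    chain = build_augmented_transition(model, ks.CountingSpec().bind(3), cap=40,
                                       absorbing=False)
    loglik = chain.emission_loglik(model, y)
    final = _dp.forward_final(loglik, chain.logpi_u, chain.s1, chain.logA_u,
                              chain.inc, chain.S, chain.absorbing)
    assert logsumexp(final) == pytest.approx(logz, abs=1e-8)


def test_constrained_samples_satisfy_event_and_match_enumeration(tiny_enumerable):
    model, y, en = tiny_enumerable
    event = ks.SegmentEvent.exactly(2)
    draws = ks.kseg_sample(model, y, ks.CountingSpec(), event, 50_000, seed=3)
    assert all(event.matches(ks.count_segments(p)) for p in draws)
    probs = en.path_probabilities(event)
    index = {k: i for i, k in enumerate(probs)}
    observed = np.zeros(len(probs))
    for p in draws:
        observed[index[tuple(p)]] += 1
    expected = np.array(list(probs.values())) * draws.shape[0]
    assert chisquare(observed, expected).pvalue > 0.001


def test_vacuously_constrained_sampling_matches_plain_posterior(tiny_enumerable):
    model, y, en = tiny_enumerable
    draws = ks.kseg_sample(model, y, ks.CountingSpec(), ks.SegmentEvent.between(1, 4),
                           20_000, seed=4)
    probs = en.path_probabilities(None)
    index = {k: i for i, k in enumerate(probs)}
    observed = np.zeros(len(probs))
    for p in draws:
        observed[index[tuple(p)]] += 1
    expected = np.array(list(probs.values())) * draws.shape[0]
    assert chisquare(observed, expected).pvalue > 0.001


def test_sampling_infeasible_event_raises(tiny_enumerable):
    model, y, _ = tiny_enumerable
    with pytest.raises(ks.InfeasibleEventError):
        ks.kseg_sample(model, y, ks.CountingSpec(), ks.SegmentEvent.greater_than(4),
                       10, seed=0)


def test_constrained_marginals_match_enumeration_and_are_consistent():
    model, y = random_instance(39, M=2, N=6)
    event = ks.SegmentEvent.at_most(2)
    cm = ks.constrained_marginals(model, y, ks.CountingSpec(), event)
    en = ks.enumerate_posterior(model, y)
    site_e, pair_e = en.marginals_under_event(event)
    assert np.allclose(cm.site, site_e, atol=1e-10)
    assert np.allclose(cm.pairwise, pair_e, atol=1e-10)
    assert cm.log_event_evidence == pytest.approx(en.event_log_evidence(event), abs=1e-10)
    # contracts: rows sum to one, pairwise margins agree with sites
    assert np.allclose(cm.site.sum(axis=1), 1.0, atol=1e-10)
    assert np.allclose(cm.pairwise.sum(axis=1), cm.site[1:], atol=1e-10)
    assert np.allclose(cm.pairwise.sum(axis=2), cm.site[:-1], atol=1e-10)


def test_vacuous_constraint_reduces_to_forward_backward():
    model, y = random_instance(40, M=3, N=25)
    fb = ks.forward_backward(model, y)
    cm = ks.constrained_marginals(model, y, ks.CountingSpec(),
                                  ks.SegmentEvent.between(1, 25))
    assert np.allclose(cm.site, fb.posterior_marginals(), atol=1e-10)
    assert cm.log_event_evidence == pytest.approx(fb.log_evidence, abs=1e-10)


def test_event_string_forms():
    assert str(ks.SegmentEvent.exactly(7)) == "c=7"
    assert str(ks.SegmentEvent.at_least(3)) == "c>2"
    assert ks.SegmentEvent.at_least(3).matches(3)
    assert not ks.SegmentEvent.at_least(3).matches(2)
    with pytest.raises(ks.InputError):
        ks.SegmentEvent.between(5, 5)
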