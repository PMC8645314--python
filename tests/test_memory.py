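import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from epmfaces.memory import (
    EpisodicPrototype,
    ExemplarTrace,
    MemoryStore,
    assimilate,
    echo,
    max_delta,
    prototypicality,
    trace_similarity,
    verify,
)
from epmfaces.synthetic import generate_trajectory, dissimilarity_matrix


def _store(threshold, half_life=math.inf, **kw):
    return MemoryStore(threshold_delta=threshold, recency_half_life=half_life, **kw)


class TestTraceSimilarity:
    def test_self_similarity_is_one(self):
        t = ExemplarTrace(np.array([2.0, -1.0, 0.5]), 0.0)
        assert trace_similarity(t.feature_vector, t) == pytest.approx(1.0)

    def test_orthogonal_vectors_give_zero(self):
        t = ExemplarTrace(np.array([0.0, 1.0]), 0.0)
        assert trace_similarity(np.array([1.0, 0.0]), t) == pytest.approx(0.0)

    def test_45_degree_cosine(self):
        t = ExemplarTrace(np.array([1.0, 1.0]), 0.0)
        assert trace_similarity(np.array([1.0, 0.0]), t) == pytest.approx(1 / math.sqrt(2))

    def test_zero_trace_vector_yields_zero(self):
        t = ExemplarTrace(np.zeros(3), 0.0)
        assert trace_similarity(np.array([1.0, 0.0, 0.0]), t) == 0.0

    def test_zero_probe_and_dim_mismatch_rejected(self):
        t = ExemplarTrace(np.ones(3), 0.0)
        with pytest.raises(ValueError):
            trace_similarity(np.zeros(3), t)
        with pytest.raises(ValueError):
            trace_similarity(np.ones(2), t)


class TestEcho:
    def test_single_matching_trace_has_unit_intensity(self):
        store = _store(1.0)
        assimilate(store, np.array([1.0, 0.0]), time=0.0)
        res = echo(np.array([1.0, 0.0]), store)
        assert res.intensity == pytest.approx(1.0)

    def test_orthogonal_probe_has_zero_intensity(self):
        store = _store(1.0)
        assimilate(store, np.array([1.0, 0.0]), time=0.0)
        assert echo(np.array([0.0, 1.0]), store).intensity == pytest.approx(0.0)

    def test_cubic_activation_hand_sum(self):
        # traces with cosine 1 and 0.5 to the probe: I = 1 + 0.5^3 = 1.125
        store = _store(100.0)
        assimilate(store, np.array([2.0, 0.0]), time=0.0)
        assimilate(store, np.array([0.5, math.sqrt(3) / 2]), time=0.0)
        res = echo(np.array([1.0, 0.0]), store)
        assert res.intensity == pytest.approx(1.125)

    def test_intensity_and_content_satisfy_definitions(self):
        store = _store(0.5, half_life=5.0)
        rng = np.random.default_rng(0)
        for t in range(6):
            assimilate(store, rng.normal(size=3), time=float(t))
        probe = rng.normal(size=3)
        res = echo(probe, store)
        manual_i = sum(w * a for _, a, w in res.per_trace)
        manual_c = sum(w * a * tr.feature_vector
                       for (_, a, w), tr in zip(res.per_trace, store.traces))
        assert res.intensity == pytest.approx(manual_i)
        assert np.allclose(res.content, manual_c)

    def test_empty_store_rejected(self):
        with pytest.raises(ValueError):
            echo(np.ones(2), _store(1.0))


class TestMaxDelta:
    def test_sole_identical_member_gives_zero(self):
        p = EpisodicPrototype(np.array([1.0, 2.0]), [ExemplarTrace(np.array([1.0, 2.0]), 0.0)], 0.0)
        assert max_delta(np.array([1.0, 2.0]), p) == 0.0

    def test_hand_computed_maximum(self):
        members = [ExemplarTrace(np.array([0.0, 0.0]), 0.0),
                   ExemplarTrace(np.array([1.0, 0.0]), 1.0)]
        p = EpisodicPrototype(np.array([0.5, 0.0]), members, 0.0)
        # distances {4.5 to centroid, 5.0, 4.0 to members} -> 5
        assert max_delta(np.array([5.0, 0.0]), p) == pytest.approx(5.0)

    def test_equidistant_members_give_common_radius(self):
        # members on the unit circle around the centroid; a probe at the
        # centre is at distance r = 1 from every member, so the maximum
        # delta equals that common radius
        members = [ExemplarTrace(np.array([1.0, 0.0]), 0.0),
                   ExemplarTrace(np.array([-1.0, 0.0]), 1.0),
                   ExemplarTrace(np.array([0.0, 1.0]), 2.0),
                   ExemplarTrace(np.array([0.0, -1.0]), 3.0)]
        p = EpisodicPrototype(np.zeros(2), members, 0.0)
        assert max_delta(np.zeros(2), p) == pytest.approx(1.0)

    def test_dimension_mismatch_rejected(self):
        p = EpisodicPrototype(np.zeros(2), [ExemplarTrace(np.zeros(2), 0.0)], 0.0)
        with pytest.raises(ValueError):
            max_delta(np.zeros(3), p)


class TestAssimilate:
    def test_first_exemplar_seeds_prototype(self):
        store = _store(1.0)
        assimilate(store, np.array([3.0, 4.0]), time=0.0, exemplar_id="a")
        assert len(store.prototypes) == 1
        assert store.prototypes[0].members[0].exemplar_id == "a"
        assert np.allclose(store.prototypes[0].centroid, [3.0, 4.0])

    def test_hand_stream_splits_at_threshold(self):
        store = _store(1.0)
        for i, x in enumerate([(0.0, 0.0), (0.1, 0.0), (5.0, 0.0)]):
            assimilate(store, np.array(x), time=float(i), exemplar_id=f"e{i + 1}")
        assert len(store.prototypes) == 2
        assert [t.exemplar_id for t in store.prototypes[0].members] == ["e1", "e2"]
        assert [t.exemplar_id for t in store.prototypes[1].members] == ["e3"]
        assert np.allclose(store.prototypes[0].centroid, [0.05, 0.0])

    def test_generous_threshold_gives_single_prototype(self):
        traj = generate_trajectory("m", n_exemplars=10, age_start=0, age_end=30,
                                   d=4, drift_params=(1.0, math.inf), seed=1)
        diameter = dissimilarity_matrix(traj).max()
        store = _store(diameter)
        for e in traj.exemplars:
            assimilate(store, e.feature_vector, time=e.capture_age)
        assert len(store.prototypes) == 1
        assert np.allclose(store.prototypes[0].centroid, traj.features.mean(axis=0))

    def test_zero_threshold_gives_one_prototype_per_distinct_exemplar(self):
        traj = generate_trajectory("m", n_exemplars=10, age_start=0, age_end=30,
                                   d=4, drift_params=(1.0, math.inf), seed=2)
        store = _store(0.0)
        for e in traj.exemplars:
            assimilate(store, e.feature_vector, time=e.capture_age)
        assert len(store.prototypes) == 10

    def test_prototype_count_nondecreasing_along_stream(self):
        store = _store(2.0)
        rng = np.random.default_rng(3)
        counts = []
        for t in range(30):
            assimilate(store, rng.normal(0, 2, 3), time=float(t))
            counts.append(len(store.prototypes))
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_rapid_update_single_novel_exposure(self):
        store = _store(1.0)
        assimilate(store, np.zeros(2), time=0.0)
        assimilate(store, np.array([50.0, 0.0]), time=1.0)
        assert len(store.prototypes) == 2
        assert len(store.prototypes[-1].members) == 1

    def test_non_chronological_stream_rejected(self):
        store = _store(1.0)
        assimilate(store, np.zeros(2), time=5.0)
        with pytest.raises(ValueError):
            assimilate(store, np.ones(2), time=4.0)

    def test_pure_leader_variant_keeps_founding_centroid(self):
        store = _store(10.0, update_centroid=False)
        assimilate(store, np.array([0.0, 0.0]), time=0.0)
        assimilate(store, np.array([4.0, 0.0]), time=1.0)
        assert np.allclose(store.prototypes[0].centroid, [0.0, 0.0])
        assert len(store.prototypes[0].members) == 2

    def test_centroid_is_running_mean_of_members(self):
        store = _store(100.0)
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(12, 4))
        for t, x in enumerate(pts):
            assimilate(store, x, time=float(t))
        assert np.allclose(store.prototypes[0].centroid, pts.mean(axis=0))


class TestPrototypicality:
    def test_single_trace_returns_its_weight(self):
        store = _store(1.0, half_life=10.0)
        assimilate(store, np.array([1.0, 1.0]), time=0.0)
        store.now = 10.0  # one half-life later
        assert prototypicality(store, np.array([1.0, 1.0])) == pytest.approx(0.5)

    def test_infinite_half_life_equals_unweighted_echo(self):
        store = _store(3.0, half_life=math.inf)
        rng = np.random.default_rng(1)
        for t in range(5):
            assimilate(store, rng.normal(size=3), time=float(t))
        probe = rng.normal(size=3)
        assert prototypicality(store, probe) == pytest.approx(echo(probe, store).intensity)

    def test_recency_weighted_hand_sum(self):
        # identical traces at t and t+h with half-life h: 1 + 0.5 = 1.5x newest weight
        store = _store(1.0, half_life=4.0)
        v = np.array([2.0, 1.0])
        assimilate(store, v, time=0.0)
        assimilate(store, v, time=4.0)
        assert prototypicality(store, v) == pytest.approx(1.5)

    def test_recency_gradient_between_prototypes(self):
        # uniform-in-time stream over two distant episodes: the recent
        # prototype's centroid must out-echo the oldest one's
        store = _store(5.0, half_life=10.0)
        rng = np.random.default_rng(2)
        base = np.array([10.0] + [0.0] * 7)
        shift = np.array([0.0, 12.0] + [0.0] * 6)
        for t in range(10):
            x = (base if t < 5 else base + shift) + rng.normal(0, 0.3, 8)
            assimilate(store, x, time=float(t * 6))
        old, new = store.prototypes
        assert prototypicality(store, new.centroid) > prototypicality(store, old.centroid)


class TestVerify:
    def test_identical_probe_matches_with_full_strength(self):
        store = _store(5.0)
        v = np.array([1.0, 2.0])
        for t in range(3):
            assimilate(store, v, time=float(t))
        res = verify(store, v, decision_threshold=0.5)
        assert res.match and res.strength == pytest.approx(3.0)

    def test_orthogonal_probe_hits_latency_ceiling(self):
        store = _store(1.0)
        assimilate(store, np.array([1.0, 0.0]), time=0.0)
        res = verify(store, np.array([0.0, 1.0]), decision_threshold=0.5,
                     rt_params=(800.0, 100.0))
        assert not res.match
        assert res.strength == pytest.approx(0.0)
        # floored at strength 1e-6: the configured maximum latency
        assert res.latency_ms == pytest.approx(800.0 - 100.0 * math.log(1e-6))

    def test_latency_linking_function(self):
        store = _store(1.0)
        assimilate(store, np.array([1.0, 0.0]), time=0.0)
        res = verify(store, np.array([1.0, 0.0]), 0.5, rt_params=(800.0, 100.0))
        assert res.strength == pytest.approx(1.0)
        assert res.latency_ms == pytest.approx(800.0)
        # engineer strength e via recency weights: 2 * 2^(-dt/h) + 1 = e
        dt = -math.log2((math.e - 1.0) / 2.0)
        store2 = _store(1.0, half_life=1.0)
        assimilate(store2, np.array([1.0, 0.0]), time=0.0)
        assimilate(store2, np.array([1.0, 0.0]), time=0.0)
        assimilate(store2, np.array([1.0, 0.0]), time=dt)
        res2 = verify(store2, np.array([1.0, 0.0]), 0.5, rt_params=(800.0, 100.0))
        assert res2.strength == pytest.approx(math.e)
        assert res2.latency_ms == pytest.approx(700.0)

    def test_latency_clamped_at_validity_floor(self):
        store = _store(5.0)
        for t in range(4):
            assimilate(store, np.array([1.0, 0.0]), time=float(t))
        res = verify(store, np.array([1.0, 0.0]), 0.5, rt_params=(300.0, 100.0))
        assert res.latency_ms == 200.0

    def test_nonpositive_slope_rejected(self):
        store = _store(1.0)
        assimilate(store, np.ones(2), time=0.0)
        with pytest.raises(ValueError):
            verify(store, np.ones(2), 0.5, rt_params=(800.0, 0.0))

    def test_strength_is_per_prototype_maximum(self):
        store = _store(1.0)
        assimilate(store, np.array([1.0, 0.0]), time=0.0)
        assimilate(store, np.array([0.0, 1.0]), time=1.0)
        res = verify(store, np.array([0.0, 1.0]), 0.5)
        assert res.best_prototype == 1
        assert res.strength == pytest.approx(1.0)


class TestSerialization:
    def test_json_roundtrip_is_lossless(self):
        store = _store(2.5, half_life=8.0)
        rng = np.random.default_rng(4)
        for t in range(7):
            assimilate(store, rng.normal(0, 2, 3), time=float(t), exemplar_id=f"e{t}")
        back = MemoryStore.from_json(store.to_json())
        assert back.to_json() == store.to_json()
        assert back.threshold_delta == store.threshold_delta
        assert len(back.prototypes) == len(store.prototypes)
        for p, q in zip(store.prototypes, back.prototypes):
            assert np.array_equal(p.centroid, q.centroid)
            assert [t.exemplar_id for t in p.members] == [t.exemplar_id for t in q.members]


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), threshold=st.floats(0.0, 20.0))
def test_every_trace_belongs_to_exactly_one_prototype(seed, threshold):
    store = MemoryStore(threshold_delta=threshold)
    rng = np.random.default_rng(seed)
    n = 15
    for t in range(n):
        assimilate(store, rng.normal(0, 3, 3), time=float(t), exemplar_id=f"e{t}")
    ids = [tr.exemplar_id for tr in store.traces]
    assert sorted(ids) == sorted(f"e{t}" for t in range(n))
    assert len(ids) == len(set(ids))
    for p in store.prototypes:
        assert np.allclose(p.centroid, np.mean([m.feature_vector for m in p.members], axis=0))
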