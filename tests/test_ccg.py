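import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from monoconn import ccg as mccg
from monoconn.ccg import (
    CrossCorrelogram,
    apply_quality_filters,
    chance_level,
    compute_ccg,
    detect_monosynaptic,
    light_response_psth,
    transmission_probability,
)
from monoconn.types import CellType, Interval

from conftest import brute_force_ccg, make_train, simulate_pair


def poisson_train(rate_hz, duration_s, rng, cell_id="c", cell_type=CellType.UNKNOWN):
    n = rng.poisson(rate_hz * duration_s)
    return make_train(np.sort(rng.uniform(0, duration_s, n)), cell_id, "r0", cell_type)


class TestComputeCcg:
    def test_single_pair_lands_in_2ms_bin(self):
        # lag 1.5 ms lies in [1.5, 2.5) -> bin centered at +2 ms
        c = compute_ccg(make_train([1.0], "a"), make_train([1.0015], "b"))
        assert c.n_ref == 1
        (idx,) = np.nonzero(c.raw_counts)
        assert c.lag_centers_ms[idx[0]] == 2.0

    def test_identical_trains_distinct_ids_pile_at_zero_lag(self):
        t = np.arange(1.0, 11.0)
        c = compute_ccg(make_train(t, "a"), make_train(t, "b"))
        assert c.raw_counts[50] == c.n_ref == 10

    def test_same_cell_id_excludes_self_pairs(self):
        t = np.arange(1.0, 11.0)
        c = compute_ccg(make_train(t, "a"), make_train(t, "a"))
        assert c.raw_counts[50] == 0

    def test_empty_reference_is_missing(self):
        assert compute_ccg(make_train([], "a"), make_train([1.0], "b"),
                           (0.0, 10.0)) is None

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_counts_match_brute_force_on_dense_random_trains(self, seed):
        rng = np.random.default_rng(seed)
        t1 = np.sort(rng.uniform(0, 60, 5000))
        t2 = np.sort(rng.uniform(0, 60, 5000))
        c = compute_ccg(make_train(t1, "a"), make_train(t2, "b"))
        np.testing.assert_array_equal(c.raw_counts, brute_force_ccg(t1, t2))

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_antisymmetry_reversing_roles_reverses_lags(self, seed):
        rng = np.random.default_rng(seed)
        a = make_train(np.sort(rng.uniform(0, 5, rng.integers(1, 200))), "a")
        b = make_train(np.sort(rng.uniform(0, 5, rng.integers(1, 200))), "b")
        ab = compute_ccg(a, b).raw_counts
        ba = compute_ccg(b, a).raw_counts
        # half-open bins make exact mirror hold up to boundary lags, which
        # have measure zero for continuous times
        np.testing.assert_array_equal(ab, ba[::-1])

    def test_restriction_to_interval(self):
        pre = make_train([1.0, 100.0], "a")
        post = make_train([1.001, 100.001], "b")
        c = compute_ccg(pre, post, (0.0, 10.0))
        assert c.n_ref == 1 and c.total_counts == 1


class TestChanceLevel:
    def test_uniform_histogram_gives_that_probability(self):
        c = CrossCorrelogram(raw_counts=np.full(101, 7), n_ref=100)
        assert chance_level(c) == pytest.approx(0.07)

    def test_zero_flanks_give_zero(self):
        raw = np.zeros(101, dtype=int)
        raw[51] = 50
        c = CrossCorrelogram(raw_counts=raw, n_ref=100)
        assert chance_level(c) == 0.0

    def test_independent_poisson_matches_closed_form(self):
        # expected flank probability = r_post * bin width = 15 * 0.001
        vals = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            pre = poisson_train(1.0, 1500.0, rng, "a")
            post = poisson_train(15.0, 1500.0, rng, "b")
            vals.append(chance_level(compute_ccg(pre, post)))
        # Poisson SE of the grand mean over 20 x 82 flank bins of ~22.5 counts
        se = 0.015 / np.sqrt(20 * 82 * 22.5)
        assert np.mean(vals) == pytest.approx(0.015, abs=5 * se)


class TestDetection:
    def test_flat_histogram_not_significant(self):
        c = CrossCorrelogram(raw_counts=np.full(101, 20), n_ref=1000)
        sig, z = detect_monosynaptic(c)
        assert not sig and np.isnan(z)  # flank SD = 0 -> undefined, flagged

    def test_planted_connection_detected(self):
        pyr, intn, sessions, _ = simulate_pair(p_trans=0.05, seed=1)
        sig, z = detect_monosynaptic(compute_ccg(pyr, intn, sessions.span))
        assert sig and z >= 3

    def test_peak_z_matches_hand_computation(self):
        rng = np.random.default_rng(0)
        raw = rng.poisson(20, size=101)
        raw[51] = 80
        c = CrossCorrelogram(raw_counts=raw, n_ref=1000)
        flank = raw[np.abs(mccg.LAG_CENTERS_MS) >= 10].astype(float)
        expected = (max(raw[51], raw[52]) - flank.mean()) / flank.std()
        _, z = detect_monosynaptic(c)
        assert z == pytest.approx(expected)

    def test_missing_ccg_not_significant(self):
        sig, z = detect_monosynaptic(None)
        assert not sig and np.isnan(z)


class TestTransmission:
    def test_perfect_relay_measures_one(self):
        pyr, intn, sessions, _ = simulate_pair(
            p_trans=1.0, seed=2, pyr_hz=1.0, int_hz=0.0
        )
        assert intn.n_spikes == pytest.approx(pyr.n_spikes, rel=0.001)
        # every relayed spike falls within 2.5 ms of its preceding pyr spike
        prev = pyr.spikes[np.searchsorted(pyr.spikes, intn.spikes) - 1]
        lag_ms = (intn.spikes - prev) * 1000
        assert np.all((lag_ms > 0) & (lag_ms <= 2.5))
        val = transmission_probability(compute_ccg(pyr, intn, sessions["FAM1"]))
        assert val == pytest.approx(1.0, abs=0.01)

    def test_independent_pair_mean_zero(self):
        vals = [
            transmission_probability(
                compute_ccg(*_indep_pair(seed), (0.0, 1500.0))
            )
            for seed in range(50)
        ]
        assert abs(np.mean(vals)) < 0.002

    def test_rate_invariance_of_null(self):
        # doubling both rates must not bias the chance-subtracted statistic
        for scale in (1.0, 2.0):
            vals = []
            for seed in range(30):
                rng = np.random.default_rng(1000 + seed)
                pre = poisson_train(1.0 * scale, 1500.0, rng, "a")
                post = poisson_train(15.0 * scale, 1500.0, rng, "b")
                vals.append(transmission_probability(compute_ccg(pre, post)))
            assert abs(np.mean(vals)) < 0.003


def _indep_pair(seed):
    rng = np.random.default_rng(seed)
    pre = poisson_train(1.0, 1500.0, rng, "a")
    post = poisson_train(15.0, 1500.0, rng, "b")
    return pre, post


class TestQualityFilters:
    def _flat_ccg(self, per_bin, n_ref=5000):
        return CrossCorrelogram(raw_counts=np.full(101, per_bin), n_ref=n_ref)

    def _poisson_ccg(self, mean, seed=0, n_ref=5000):
        rng = np.random.default_rng(seed)
        return CrossCorrelogram(raw_counts=rng.poisson(mean, 101), n_ref=n_ref)

    def test_below_count_threshold_fails_with_reason(self):
        c1 = self._poisson_ccg(999 / 101.0, seed=1)
        while c1.total_counts >= 1000:
            c1 = self._poisson_ccg(9.0, seed=2)
        passes, reasons = apply_quality_filters(c1, None)
        assert not passes and reasons == ["min_counts"]

    def test_thousand_counts_flat_flanks_pass(self):
        passes, reasons = apply_quality_filters(self._flat_ccg(10), None)
        assert passes and reasons == []

    def test_overdispersed_flanks_fail(self):
        rng = np.random.default_rng(4)
        raw = np.zeros(101, dtype=int)
        raw[rng.integers(0, 101, 30)] = 100  # lumpy -> SD/mean > 1/3
        c = CrossCorrelogram(raw_counts=raw, n_ref=5000)
        passes, reasons = apply_quality_filters(c, c)
        assert not passes and reasons == ["dispersion"]

    def test_either_familiar_session_can_qualify(self):
        passes, _ = apply_quality_filters(None, self._flat_ccg(10))
        assert passes


class TestLightPsth:
    def _pulses(self, sessions):
        return sessions.lights_within("REST")

    def test_constant_rate_cell_unmodulated(self):
        rng = np.random.default_rng(0)
        train = poisson_train(10.0, 1080.0, rng, "c")
        pulses = [(t, t + 0.5) for t in np.arange(0, 1077, 3.0)]
        edges, prob, cls = light_response_psth(train, pulses)
        assert cls == "unmodulated"
        assert prob.mean() == pytest.approx(10.0 * 0.020, rel=0.1)

    def test_suppressed_cell_classified(self):
        trains, sessions, truth = _light_dataset(seed=5)
        cells = truth.cells.drop_duplicates("cell_id").set_index("cell_id")
        pulses = sessions.lights_within("REST")
        seen = {"suppressed": 0, "activated": 0}
        for t in trains:
            true_cls = cells.loc[t.cell_id, "light_class"]
            if true_cls not in seen:
                continue
            _, _, cls = light_response_psth(t, pulses)
            if cls == true_cls:
                seen[true_cls] += 1
        assert seen["suppressed"] >= 1 and seen["activated"] >= 1

    def test_no_pulses_is_error(self):
        with pytest.raises(ValueError, match="at least one pulse"):
            light_response_psth(make_train([1.0]), [])


def _light_dataset(seed):
    from monoconn.simulate import LightConfig, SimConfig, simulate_dataset

    cfg = SimConfig(
        n_animals=1, n_pyr=6, n_int=3, seed=seed,
        pyr_rate_lognorm=(np.log(3.0), 0.0),
        int_rate_lognorm=(np.log(15.0), 0.0),
        animal_random_intercept_sd=0.0,
        faml_light=LightConfig(
            fraction_suppressed_pyr=0.5, fraction_disinhibited_pyr=0.3,
            fraction_suppressed_int=0.67, suppression_factor=0.1,
            enhancement_factor=2.5,
        ),
    )
    return simulate_dataset(cfg)
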