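"""Departure-model mechanics: probabilities, replicates, batches."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from collmove import (
    NetworkError,
    SimulationConfig,
    SocialNetwork,
    build_continuum_network,
    build_random_network,
    event_driven_replicate,
    initiation_probability,
    joining_probability,
    run_batch,
    run_replicate,
)
from collmove.simulation import read_batch, write_batch

LAM = 0.00007


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"lam": 0.0},
            {"lam": 1.5},
            {"M": -0.1},
            {"kernel": "K4"},
            {"stop_window": 0},
            {"replicates": 0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestInitiation:
    def test_collective_probability_scales_with_group_size(self):
        cfg = SimulationConfig()
        assert initiation_probability(cfg, 10) == pytest.approx(0.0007)
        assert initiation_probability(cfg, 1) == pytest.approx(0.00007)

    def test_mean_initiation_latency_matches_geometric_closed_form(
        self, star_calibration
    ):
        # any kernel: the pre-initiation phase only involves lam
        records = star_calibration.batches["K1"]
        lat = np.array([rec.initiation_time for rec in records if not rec.void])
        expected = 1.0 / (1.0 - (1.0 - LAM) ** 10)  # ~1428.9 s
        se = lat.std(ddof=1) / np.sqrt(lat.size)
        assert abs(lat.mean() - expected) < 3 * se

    def test_initiator_identity_is_uniform(self, star_calibration):
        records = star_calibration.batches["K1"]
        counts = {}
        for rec in records:
            counts[rec.initiator] = counts.get(rec.initiator, 0) + 1
        chi2 = sps.chisquare(list(counts.values()))
        assert len(counts) == 10
        assert chi2.pvalue > 1e-3


class TestJoiningProbability:
    def test_no_movers_means_intrinsic_rate_only(self, star):
        for kernel in ("K1", "K2", "K3"):
            cfg = SimulationConfig(kernel=kernel)
            assert joining_probability(star, set(), "c1", cfg) == pytest.approx(LAM)

    def test_star_kernels_after_central_departure(self, star):
        assert joining_probability(
            star, {"C"}, "c1", SimulationConfig(kernel="K1")
        ) == pytest.approx(LAM + 0.002)
        # j=1 mover, N-j=9 resters: K2 and K3 coincide
        for kernel in ("K2", "K3"):
            assert joining_probability(
                star, {"C"}, "c1", SimulationConfig(kernel=kernel)
            ) == pytest.approx(LAM + 0.002 * 9)

    def test_already_moving_agent_rejected(self, star):
        with pytest.raises(NetworkError, match="already moving"):
            joining_probability(star, {"C"}, "C", SimulationConfig())

    @given(
        seed=st.integers(0, 500),
        movers=st.sets(st.integers(1, 7), min_size=0, max_size=6),
        extra=st.integers(1, 7),
    )
    def test_k1_probability_never_drops_when_a_mover_is_added(
        self, seed, movers, extra
    ):
        net = build_random_network(8, p=0.6, seed=seed)
        cfg = SimulationConfig(kernel="K1")
        resting = "i8"
        a = joining_probability(net, {f"i{m}" for m in movers}, resting, cfg)
        b = joining_probability(
            net, {f"i{m}" for m in movers | {extra}}, resting, cfg
        )
        assert b >= a >= LAM


class TestReplicate:
    def test_single_agent_departs_alone(self):
        net = SocialNetwork(("solo",), np.zeros((1, 1)))
        rec = run_replicate(net, SimulationConfig(lam=0.01), np.random.default_rng(0))
        assert rec.n_departed == 1
        assert rec.complete
        assert rec.initiator == "solo"

    def test_identical_seed_gives_identical_events(self, star):
        cfg = SimulationConfig(kernel="K3")
        a = run_replicate(star, cfg, np.random.default_rng(42))
        b = run_replicate(star, cfg, np.random.default_rng(42))
        assert a == b

    def test_no_gap_exceeds_stop_window(self, star_calibration):
        for records in star_calibration.batches.values():
            for rec in records[:2000]:
                assert all(g <= 300 for g in rec.gaps())

    def test_timestamps_non_decreasing_and_initiator_first(self, star_calibration):
        for rec in star_calibration.batches["K3"][:2000]:
            times = [t for _, t in rec.events]
            assert times == sorted(times)
            assert rec.n_departed == len(rec.events)

    def test_void_when_no_initiation_before_time_cap(self):
        net = build_continuum_network(10, 1.0)
        cfg = SimulationConfig(lam=1e-9, max_time=100)
        rec = run_replicate(net, cfg, np.random.default_rng(1))
        assert rec.void and rec.n_departed == 0

    def test_truncation_at_time_cap_is_flagged(self):
        net = build_continuum_network(3, 1.0)
        cfg = SimulationConfig(lam=0.9, M=0.0, max_time=1)
        flagged = []
        for seed in range(60):
            rec = run_replicate(net, cfg, np.random.default_rng(seed))
            if not rec.complete and not rec.void:
                flagged.append(rec)
        assert flagged  # movements cut mid-way are never silent
        assert all(rec.truncated for rec in flagged)


class TestEventDrivenOracle:
    def test_m_zero_inter_departure_gaps_are_geometric(self):
        """With no mimetism, the next-departure gap for R resting agents is
        geometric with p = 1 - (1-lam)^R (closed form)."""
        lam = 0.002
        net = build_continuum_network(10, 1 / 9)
        cfg = SimulationConfig(lam=lam, M=0.0, stop_window=10_000)
        first_gaps = []
        for seed in range(3000):
            rec = event_driven_replicate(net, cfg, np.random.default_rng(seed))
            if rec.n_departed >= 2:
                first_gaps.append(rec.first_joiner_latency)
        p = 1.0 - (1.0 - lam) ** 9
        expected = 1.0 / p
        got = np.mean(first_gaps)
        se = np.std(first_gaps, ddof=1) / np.sqrt(len(first_gaps))
        assert abs(got - expected) < 3 * se

    def test_single_agent_time_is_geometric_with_psi01(self):
        lam = 0.01
        net = SocialNetwork(("solo",), np.zeros((1, 1)))
        cfg = SimulationConfig(lam=lam)
        times = [
            event_driven_replicate(net, cfg, np.random.default_rng(s)).initiation_time
            for s in range(4000)
        ]
        se = np.std(times, ddof=1) / np.sqrt(len(times))
        assert abs(np.mean(times) - 1 / lam) < 3 * se


class TestBatch:
    def test_batches_are_reproducible_and_sized(self, equal):
        cfg = SimulationConfig(kernel="K3", replicates=100, seed=1)
        a = run_batch(equal, cfg)
        b = run_batch(equal, cfg)
        assert len(a) == 100
        assert a == b

    def test_replicate_indices_attached(self, equal):
        cfg = SimulationConfig(replicates=5, seed=3)
        records = run_batch(equal, cfg)
        assert [rec.replicate for rec in records] == list(range(5))

    def test_round_trip_through_batch_files(self, tmp_path, star):
        cfg = SimulationConfig(kernel="K3", replicates=50, seed=9)
        records = run_batch(star, cfg)
        write_batch(records, tmp_path / "batch.tsv")
        back = read_batch(tmp_path / "batch.tsv", n_total=star.n)
        assert [r.events for r in back] == [r.events for r in records]
        assert [r.void for r in back] == [r.void for r in records]
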