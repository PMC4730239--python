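"""Unit and property tests for the gene-flow-matrix track-length theory."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from admixtrack import (
    AdmixtureMatrix,
    TwoWayModelSpec,
    build_matrix,
    build_trajectory,
    moments,
    tail_probability,
    track_length_distribution,
    truncate,
)
from admixtrack.core_model import TrackLengthDistribution


def hi_matrix(m, T):
    vals = np.zeros((2, T))
    vals[:, 0] = (m, 1 - m)
    return AdmixtureMatrix(vals)


class TestMatrixValidation:
    def test_founding_column_must_sum_to_one(self):
        with pytest.raises(ValueError, match="founding column"):
            AdmixtureMatrix(np.array([[0.3, 0.0], [0.3, 0.0]]))

    def test_later_column_oversum_names_column(self):
        vals = np.array([[0.5, 0.7], [0.5, 0.7]])
        with pytest.raises(ValueError, match="t=2"):
            AdmixtureMatrix(vals)

    def test_negative_entry_names_column(self):
        vals = np.array([[0.5, -0.1], [0.5, 0.0]])
        with pytest.raises(ValueError, match="column 2"):
            AdmixtureMatrix(vals)

    def test_single_ancestry_rejected(self):
        with pytest.raises(ValueError, match="K >= 2"):
            AdmixtureMatrix(np.ones((1, 3)))

    def test_roundtrip_frame_and_dict(self):
        M = build_matrix(TwoWayModelSpec("GA", 0.3, 5), labels=("AFR", "EUR"))
        M2 = AdmixtureMatrix.from_frame(M.to_frame())
        np.testing.assert_array_equal(M.values, M2.values)
        assert M2.labels == ("AFR", "EUR")
        M3 = AdmixtureMatrix.from_dict(M.to_dict())
        np.testing.assert_array_equal(M.values, M3.values)


class TestTrajectory:
    def test_hi_constant_trajectory(self):
        traj = build_trajectory(hi_matrix(0.2, 3))
        np.testing.assert_allclose(traj.H[0], 0.2)
        np.testing.assert_allclose(traj.s[0], [0.2, 0.0, 0.0])
        assert traj.u[0, 0] == pytest.approx(0.8 * 3)

    def test_two_generation_hand_recursion(self):
        # founding (0.5, 0.5); second wave (0.2, 0) replaces 20%
        M = AdmixtureMatrix(np.array([[0.5, 0.2], [0.5, 0.0]]))
        traj = build_trajectory(M)
        np.testing.assert_allclose(traj.h, [0.0, 0.8])
        np.testing.assert_allclose(traj.H[0], [0.5, 0.6])
        np.testing.assert_allclose(traj.s[0], [0.4, 0.2])
        np.testing.assert_allclose(traj.s[1], [0.4, 0.0])
        np.testing.assert_allclose(traj.u[0], [0.9, 0.4])
        assert traj.u[1, 0] == pytest.approx(1.1)
        # junction-count identity: both ancestries see equally many junctions
        assert np.dot(traj.s[0], traj.u[0]) == pytest.approx(
            np.dot(traj.s[1], traj.u[1])
        )
        assert np.dot(traj.s[0], traj.u[0]) == pytest.approx(0.44)

    def test_hi_effective_recombination_convention(self):
        # the founding cohort accumulates (1-m) per generation over all T
        traj = build_trajectory(hi_matrix(0.1, 200))
        assert traj.u[0, 0] == pytest.approx(180.0)

    def test_invariants_on_random_matrices(self, rng_matrices):
        for M in rng_matrices:
            traj = build_trajectory(M)
            T = M.n_generations
            np.testing.assert_allclose(traj.H.sum(axis=0), np.ones(T), atol=1e-12)
            np.testing.assert_allclose(
                traj.s.sum(axis=1), traj.H[:, -1], atol=1e-12
            )
            assert np.all(np.diff(traj.u, axis=1) <= 1e-12)
            if M.n_ancestries == 2:
                assert np.dot(traj.s[0], traj.u[0]) == pytest.approx(
                    np.dot(traj.s[1], traj.u[1]), abs=1e-10
                )

    def test_two_population_mean_ratio_is_proportion_ratio(self, rng_matrices):
        for M in rng_matrices:
            if M.n_ancestries != 2:
                continue
            traj = build_trajectory(M)
            if traj.H[0, -1] <= 0 or traj.H[1, -1] <= 0:
                continue
            m1, _ = moments(traj, 0)
            m2, _ = moments(traj, 1)
            assert m1 / m2 == pytest.approx(
                traj.H[0, -1] / traj.H[1, -1], abs=1e-10
            )


class TestDistribution:
    def test_hi_is_unit_rate_exponential(self):
        traj = build_trajectory(hi_matrix(0.5, 2))
        d = track_length_distribution(traj, 0)
        assert d.rates.shape == (1,)
        assert d.rates[0] == pytest.approx(1.0)
        assert d.pdf(1.0) == pytest.approx(np.exp(-1), rel=1e-12)

    def test_ga_two_generation_mixture(self):
        traj = build_trajectory(build_matrix(TwoWayModelSpec("GA", 0.5, 2)))
        d = track_length_distribution(traj, 0)
        np.testing.assert_allclose(sorted(d.rates), [0.5, 1.0])
        np.testing.assert_allclose(sorted(d.weights), [1 / 3, 2 / 3])
        assert d.mean() == pytest.approx(4 / 3)

    def test_density_normalizes(self, rng_matrices):
        for M in rng_matrices[:15]:
            traj = build_trajectory(M)
            for i in range(M.n_ancestries):
                if traj.H[i, -1] <= 0:
                    continue
                d = track_length_distribution(traj, i)
                total, _ = quad(d.pdf, 0, np.inf, limit=200)
                assert total == pytest.approx(1.0, abs=1e-6)
                assert d.weights.sum() == pytest.approx(1.0, abs=1e-12)
                assert np.all(d.rates > 0)

    def test_absent_ancestry_raises(self):
        M = AdmixtureMatrix(np.array([[0.0, 0.0], [1.0, 0.0]]))
        traj = build_trajectory(M)
        with pytest.raises(ValueError, match="absent"):
            track_length_distribution(traj, 0)

    def test_lookup_by_label(self):
        M = build_matrix(TwoWayModelSpec("HI", 0.3, 5), labels=("AFR", "EUR"))
        traj = build_trajectory(M)
        d = track_length_distribution(traj, "AFR")
        assert d.ancestry == "AFR"
        with pytest.raises(KeyError):
            track_length_distribution(traj, "NEA")


class TestTruncation:
    def test_zero_threshold_is_identity(self):
        traj = build_trajectory(hi_matrix(0.3, 10))
        d = track_length_distribution(traj, 0)
        dt = truncate(d, 0.0)
        ls = np.linspace(0.01, 1, 50)
        np.testing.assert_allclose(dt.pdf(ls), d.pdf(ls))

    def test_hi_memorylessness(self):
        # single exponential: conditioning on L > C just shifts the density
        traj = build_trajectory(hi_matrix(0.1, 200))
        d = truncate(track_length_distribution(traj, 0), 0.02)
        for l in (0.021, 0.05, 0.1):
            assert d.pdf(l) == pytest.approx(180 * np.exp(-180 * (l - 0.02)))

    def test_truncated_density_renormalizes(self):
        traj = build_trajectory(build_matrix(TwoWayModelSpec("GA", 0.5, 2)))
        d = track_length_distribution(traj, 0)
        norm = (2 / 3) * np.exp(-0.5) + (1 / 3) * np.exp(-0.25)
        dt = truncate(d, 0.5)
        assert dt.pdf(0.7) == pytest.approx(d.pdf(0.7) / norm)
        total, _ = quad(dt.pdf, 0.5, np.inf, limit=200)
        assert total == pytest.approx(1.0, abs=1e-8)
        assert dt.pdf(0.4) == 0.0

    def test_hopeless_threshold_raises(self):
        traj = build_trajectory(hi_matrix(0.1, 200))
        d = track_length_distribution(traj, 0)
        with pytest.raises(ValueError, match="smaller threshold"):
            truncate(d, 50.0)


class TestTailAndMoments:
    def test_hi_printed_tail_value(self):
        traj = build_trajectory(hi_matrix(0.1, 200))
        d = track_length_distribution(traj, 0)
        assert tail_probability(d, 0.02) == pytest.approx(
            np.exp(-180 * 0.02), rel=1e-12
        )

    def test_tail_at_zero_is_one(self, rng_matrices):
        for M in rng_matrices[:20]:
            traj = build_trajectory(M)
            d = track_length_distribution(traj, int(np.argmax(traj.H[:, -1])))
            assert tail_probability(d, 0.0) == pytest.approx(1.0)

    def test_ga_tail_hand_value(self):
        traj = build_trajectory(build_matrix(TwoWayModelSpec("GA", 0.5, 2)))
        d = track_length_distribution(traj, 0)
        expected = (2 / 3) * np.exp(-1.0) + (1 / 3) * np.exp(-0.5)
        assert tail_probability(d, 1.0) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("m,T", [(0.5, 10), (0.1, 200), (0.3, 7)])
    def test_hi_moments_closed_form(self, m, T):
        traj = build_trajectory(hi_matrix(m, T))
        mean, var = moments(traj, 0)
        rate = (1 - m) * T
        assert mean == pytest.approx(1 / rate, rel=1e-12)
        assert var == pytest.approx(1 / rate**2, rel=1e-12)

    def test_ga_mean_hand_value(self):
        traj = build_trajectory(build_matrix(TwoWayModelSpec("GA", 0.5, 2)))
        mean, _ = moments(traj, 0)
        assert mean == pytest.approx(0.5 / 0.375)


class TestConditionalIdentities:
    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        name=st.sampled_from(["HI", "GA", "CGFR", "CGFD"]),
        m=st.floats(0.05, 0.5),
        T=st.integers(1, 120),
        C=st.floats(0.0, 0.05),
        dl=st.floats(1e-4, 0.5),
    )
    def test_truncation_consistency(self, name, m, T, C, dl):
        """Conditioning on L > C rescales survival and density by P(L > C)
        and leaves the tail shape intact: sf(l | L > C) = sf(l)/sf(C)."""
        traj = build_trajectory(build_matrix(TwoWayModelSpec(name, m, T)))
        d = track_length_distribution(traj, 0)
        p_c = tail_probability(d, C)
        if p_c < 1e-12:
            return
        dt = truncate(d, C)
        l = C + dl
        assert dt.sf(l) == pytest.approx(tail_probability(d, l) / p_c, rel=1e-9)
        assert dt.pdf(l) == pytest.approx(d.pdf(l) / p_c, rel=1e-9)
        assert tail_probability(d, 0.0) == pytest.approx(1.0, abs=1e-12)


class TestDistributionObject:
    def test_invalid_mixture_rejected(self):
        with pytest.raises(ValueError):
            TrackLengthDistribution(rates=[0.0, 1.0], weights=[0.5, 0.5])
        with pytest.raises(ValueError):
            TrackLengthDistribution(rates=[1.0, 2.0], weights=[0.7, 0.7])

    def test_logpdf_matches_log_of_pdf(self):
        traj = build_trajectory(build_matrix(TwoWayModelSpec("GA", 0.3, 20)))
        d = track_length_distribution(traj, 0)
        ls = np.geomspace(1e-3, 2, 40)
        np.testing.assert_allclose(d.logpdf(ls), np.log(d.pdf(ls)), rtol=1e-10)
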