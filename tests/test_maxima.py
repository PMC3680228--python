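"""Wavelet decomposition, modulus maxima and cross-scale persistence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wmd.maxima import (LocalMaximum, ScaleCoefficients, decompose,
                        default_tolerance, find_local_maxima,
                        link_across_scales, persistent_maxima,
                        _analysis_filters)
from wmd.synth import _bandlimited_noise, make_template


def brute_force_maxima(coeffs):
    """Exhaustive O(N) scan for strict interior modulus peaks (oracle)."""
    a = np.abs(np.asarray(coeffs, dtype=float))
    out = []
    for n in range(1, len(a) - 1):
        if a[n] > a[n - 1] and a[n] > a[n + 1] and a[n] > 0:
            out.append((n, a[n]))
    return out


def _mx(coeffs, scale=1):
    return find_local_maxima(ScaleCoefficients(scale, np.asarray(coeffs, float)))


class TestDecompose:
    def test_zero_signal_gives_zero_coefficients(self):
        for sc in decompose(np.zeros(512), 4):
            np.testing.assert_array_equal(sc.coefficients, 0.0)
            assert len(sc.coefficients) == 512

    def test_linearity(self, rng):
        x = rng.standard_normal(512)
        a = decompose(x, 3)
        b = decompose(2.5 * x, 3)
        for sa, sb in zip(a, b):
            np.testing.assert_allclose(sb.coefficients, 2.5 * sa.coefficients,
                                       rtol=1e-12, atol=1e-12)

    def test_impulse_finest_scale_equals_filter(self):
        """Finest detail of a centered impulse reproduces the (reversed) taps."""
        x = np.zeros(256)
        x[128] = 1.0
        _, hi = _analysis_filters("bior3.3", "spline")
        finest = decompose(x, 2)[0].coefficients
        nz = np.flatnonzero(np.abs(finest) > 1e-12)
        assert len(nz) == len(hi)
        # convolution convention: the impulse response is the filter itself,
        # centered on the impulse up to the fixed alignment offset
        np.testing.assert_allclose(finest[nz], hi, atol=1e-12)
        assert abs(int(np.argmax(np.abs(finest))) - 128) <= len(hi) // 2

    def test_too_short_signal_names_feasible_depth(self):
        with pytest.raises(ValueError, match="maximum feasible depth"):
            decompose(np.zeros(40), 4)

    def test_dual_side_filters_selectable(self, rng):
        x = rng.standard_normal(512)
        a = decompose(x, 2, analysis_side="spline")[0].coefficients
        b = decompose(x, 2, analysis_side="dual")[0].coefficients
        assert not np.allclose(a, b)


class TestFindLocalMaxima:
    def test_monotone_ramp_has_no_peaks(self):
        assert _mx(np.arange(10.0)) == []

    def test_modulus_convention(self):
        got = _mx([0.0, 1.0, 0.0, -2.0, 0.0])
        assert [(m.position, m.magnitude) for m in got] == [(1, 1.0), (3, 2.0)]

    def test_plateau_is_not_a_peak(self):
        assert _mx([0.0, 1.0, 1.0, 0.0]) == []

    def test_endpoints_never_returned(self):
        got = _mx([5.0, 1.0, 4.0])
        assert all(0 < m.position < 2 for m in got)

    def test_matches_brute_force_on_random_sequences(self, rng):
        for _ in range(50):
            # half-integer values provoke plateaus and exact ties
            c = rng.integers(-4, 5, size=256) * 0.5
            got = [(m.position, m.magnitude) for m in _mx(c)]
            assert got == brute_force_maxima(c)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.integers(min_value=-5, max_value=5), min_size=3,
                    max_size=60))
    def test_matches_brute_force_property(self, values):
        c = np.asarray(values, dtype=float)
        got = [(m.position, m.magnitude) for m in _mx(c)]
        assert got == brute_force_maxima(c)


class TestLinking:
    def test_single_event_dominant_chain_at_event(self):
        """An isolated singularity yields a dominant complete chain at its position."""
        x = np.zeros(2048)
        x[1000] = 1.0
        x[1001] = 0.4  # asymmetric: a perfect delta ties the antisymmetric filter
        chains = link_across_scales(
            [find_local_maxima(s) for s in decompose(x, 4)])
        assert chains
        best = max(chains, key=lambda c: c.finest_magnitude)
        assert abs(best.finest_position - 1000) <= 2
        # drift between adjacent scales stays within the linking tolerance
        for s, (p, q) in enumerate(zip(best.positions, best.positions[1:]), start=1):
            assert abs(q - p) <= default_tolerance(s)

    def test_maxima_only_at_finest_scale_gives_no_chains(self):
        per_scale = [
            [LocalMaximum(position=100, scale_index=1, magnitude=1.0)],
            [], [], [],
        ]
        assert link_across_scales(per_scale) == []

    def test_two_distant_events_give_two_chains(self):
        x = np.zeros(4096)
        for p in (1000, 3000):
            x[p] = 1.0
            x[p + 1] = 0.4
        chains = link_across_scales(
            [find_local_maxima(s) for s in decompose(x, 4)])
        tops = sorted(chains, key=lambda c: -c.finest_magnitude)[:2]
        assert sorted(abs(c.finest_position - p)
                      for c, p in zip(sorted(tops, key=lambda c: c.finest_position),
                                      (1000, 3000))) <= [2, 2]

    def test_each_maximum_used_at_most_once(self, rng):
        x = rng.standard_normal(2048)
        per_scale = [find_local_maxima(s) for s in decompose(x, 4)]
        chains = link_across_scales(per_scale)
        for s in range(4):
            members = [c.positions[s] for c in chains]
            assert len(members) == len(set(members))


class TestPersistentMaxima:
    def test_zero_signal_empty(self):
        assert persistent_maxima(np.zeros(1024), 4) == []

    def test_scaling_preserves_positions_scales_magnitudes(self, rng):
        x = rng.standard_normal(2048)
        a = persistent_maxima(x, 4)
        b = persistent_maxima(3.0 * x, 4)
        assert [p for p, _ in a] == [p for p, _ in b]
        np.testing.assert_allclose([m for _, m in b],
                                   [3.0 * m for _, m in a], rtol=1e-12)

    def test_translation_covariance(self, rng):
        x = rng.standard_normal(2048)
        k = 64
        shifted = np.concatenate([x[-k:], x[:-k]])
        a = {p for p, _ in persistent_maxima(x, 4)}
        b = {p for p, _ in persistent_maxima(shifted, 4)}
        interior = {p for p in a if 200 <= p < 2048 - 200}
        moved = {p + k for p in interior}
        assert len(moved & b) / len(moved) > 0.9

    def test_sorted_by_position_positive_magnitudes(self, rng):
        got = persistent_maxima(rng.standard_normal(2048), 4)
        positions = [p for p, _ in got]
        assert positions == sorted(positions)
        assert all(m > 0 for _, m in got)

    def test_muaps_in_noise_add_chains_at_muap_positions(self):
        """Large MUAPs in white noise add chains whose biggest magnitudes sit on them."""
        rng = np.random.default_rng(8)
        noise = _bandlimited_noise(8192, 1024.0, 0.1, rng)
        events = np.sort(rng.choice(np.arange(200, 7900, 100), 10, replace=False))
        tpl = make_template(10.0).samples
        x = noise.copy()
        for p in events:
            x[p: p + 10] += tpl  # peak amplitude 10x the noise RMS
        with_events = persistent_maxima(x, 4)
        assert len(with_events) >= 10
        mags = np.array([m for _, m in with_events])
        pos = np.array([p for p, _ in with_events])
        top10 = pos[np.argsort(mags)[-10:]]
        for t in top10:
            assert np.min(np.abs(events + 5 - t)) <= 16
        # and every event is marked by at least one chain
        for p in events:
            assert np.min(np.abs(pos - (p + 5))) <= 16

    def test_persistence_rejects_noise_transients(self, rng):
        """Chains per second on pure noise stay below the scale-1 maxima rate."""
        x = rng.standard_normal(8192)
        n_scale1 = len(find_local_maxima(decompose(x, 4)[0]))
        n_chains = len(persistent_maxima(x, 4))
        assert n_chains < n_scale1
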