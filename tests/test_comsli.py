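import numpy as np
import pytest

from conftest import fold_phantom, single_pixel_gt
from fibremap.angles import orientation_separation
from fibremap.comsli import (
    ComsliParams,
    PeakSet,
    average_intensity_map,
    compute_fom,
    detect_peaks,
    mask_fom,
    orientations_from_peaks,
    pair_peaks,
    peak_distance_map,
)
from fibremap.containers import AngularStack
from fibremap.phantom import FibrePopulation, PhantomSpec, generate_phantom
from fibremap.simulate import (
    make_schedule,
    profile_for_populations,
    simulate_comsli_stack,
)

SCHED = make_schedule(15.0)
PSI = np.array(SCHED.azimuths_deg)


def brute_force_peaks(values, prominence_frac):
    """Independent circular local-maximum + prominence computation.

    A sample is a peak when it strictly exceeds its predecessor and is at
    least its successor (circularly).  Its prominence is its height above
    the higher of the two minima encountered walking each way around the
    circle until a strictly higher sample (falling back to the circular
    minimum for the global maximum).
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    amplitude = values.max() - values.min()
    if amplitude <= 0:
        return []
    peaks = []
    for i in range(n):
        if not (values[i] > values[(i - 1) % n] and values[i] >= values[(i + 1) % n]):
            continue
        bases = []
        for step in (1, -1):
            low = values[i]
            for k in range(1, n):
                v = values[(i + step * k) % n]
                if v > values[i]:
                    break
                low = min(low, v)
            bases.append(low)
        prominence = values[i] - max(bases)
        if prominence >= prominence_frac * amplitude:
            peaks.append((i, prominence))
    return peaks


class TestDetectPeaks:
    def test_flat_profile_yields_nothing(self):
        assert len(detect_peaks(np.ones(24), PSI)) == 0

    def test_two_clear_peaks_kept(self):
        prof = profile_for_populations((FibrePopulation(135.0),), PSI)
        peaks = detect_peaks(prof, PSI)
        assert len(peaks) == 2
        assert np.allclose(peaks.positions, [45.0, 225.0])

    def test_low_prominence_bump_rejected(self):
        prof = profile_for_populations((FibrePopulation(0.0),), PSI)
        amplitude = prof.max() - prof.min()
        bump = 0.05 * amplitude * np.exp(-0.5 * ((PSI - 180.0) / 8.0) ** 2)
        peaks = detect_peaks(prof + bump, PSI)
        assert len(peaks) == 2  # the 5% bump falls below the 8% filter
        strong = detect_peaks(prof + 4.0 * bump, PSI)
        assert len(strong) == 3

    def test_wraparound_peak_detected(self):
        prof = profile_for_populations((FibrePopulation(90.0),), PSI)
        peaks = detect_peaks(prof, PSI)  # maxima at 0° and 180°
        assert np.allclose(peaks.positions, [0.0, 180.0])

    def test_off_grid_peak_refined(self):
        fine_truth = 40.0  # peaks at 130° and 310°, off the 15° grid
        prof = profile_for_populations((FibrePopulation(fine_truth),), PSI)
        peaks = detect_peaks(prof, PSI)
        assert len(peaks) == 2
        # a 15° grid over an 8°-sd peak leaves a sub-grid interpolation bias
        assert abs(peaks.positions[0] - 130.0) < 2.5
        assert abs(peaks.positions[1] - 310.0) < 2.5

    def test_short_profile_rejected(self):
        with pytest.raises(ValueError):
            detect_peaks(np.ones(4))

    def test_matches_brute_force_oracle(self, rng):
        """Tiled scipy detection equals exhaustive circular enumeration."""
        for _ in range(200):
            n_pop = rng.integers(1, 4)
            pops = tuple(
                FibrePopulation(
                    float(rng.uniform(0, 180)),
                    float(rng.uniform(0, 45)),
                    float(rng.uniform(0.3, 1.5)),
                )
                for _ in range(n_pop)
            )
            prof = profile_for_populations(pops, PSI)
            prof += rng.normal(0, 0.02, size=prof.shape)
            got = detect_peaks(prof, PSI, refinement="none")
            expected = brute_force_peaks(prof, 0.08)
            assert len(got) == len(expected)
            exp_pos = PSI[[i for i, _ in expected]]
            assert np.allclose(np.sort(got.positions), np.sort(exp_pos))
            exp_prom = np.array([p for _, p in sorted(expected)])
            assert np.allclose(got.prominences, exp_prom)


class TestPairPeaks:
    def test_exact_pair(self):
        peaks = PeakSet([45.0, 225.0], [1.0, 1.0])
        pairs, lone = pair_peaks(peaks)
        assert pairs == [(0, 1)] and lone == []

    def test_two_pairs(self):
        peaks = PeakSet([0.0, 90.0, 180.0, 270.0], [1.0] * 4)
        pairs, lone = pair_peaks(peaks)
        assert sorted(pairs) == [(0, 2), (1, 3)] and lone == []

    def test_outside_tolerance_stays_lone(self):
        peaks = PeakSet([0.0, 120.0], [1.0, 1.0])
        pairs, lone = pair_peaks(peaks)
        assert pairs == [] and lone == [0, 1]

    def test_closest_to_180_wins(self):
        # 10° could pair with 185° (dev 5) or 200° (dev 10): greedy takes 185
        peaks = PeakSet([10.0, 185.0, 200.0], [1.0, 1.0, 1.0])
        pairs, lone = pair_peaks(peaks)
        assert pairs == [(0, 1)] and lone == [2]


class TestOrientationsFromPeaks:
    def test_pair_midpoint(self):
        peaks = PeakSet([45.0, 225.0], [1.0, 1.0])
        oris, seps, overflow = orientations_from_peaks(peaks, [(0, 1)], [])
        assert oris == pytest.approx([135.0])
        assert seps == pytest.approx([180.0])
        assert not overflow

    def test_two_pairs_two_orientations(self):
        peaks = PeakSet([0.0, 60.0, 180.0, 240.0], [1.0] * 4)
        oris, _, _ = orientations_from_peaks(peaks, [(0, 2), (1, 3)], [])
        assert sorted(oris) == pytest.approx([90.0, 150.0])

    def test_lone_peak_perpendicular_rule(self):
        peaks = PeakSet([120.0], [1.0])
        oris, seps, _ = orientations_from_peaks(peaks, [], [0])
        assert oris == pytest.approx([30.0])
        assert np.isnan(seps[0])

    def test_close_orientations_merge(self):
        peaks = PeakSet([0.0, 8.0, 180.0, 188.0], [1.0] * 4)
        oris, _, _ = orientations_from_peaks(peaks, [(0, 2), (1, 3)], [])
        assert len(oris) == 1
        assert orientation_separation(oris[0], 94.0) < 1e-6

    def test_overflow_flagged_and_capped(self):
        positions = [0.0, 45.0, 90.0, 135.0, 180.0, 225.0, 270.0, 315.0]
        peaks = PeakSet(positions, [1.0] * 8)
        pairs, lone = pair_peaks(peaks)
        oris, _, overflow = orientations_from_peaks(peaks, pairs, lone)
        assert len(oris) == 3
        assert overflow


class TestComputeFom:
    def test_unidirectional_phantom(self):
        spec = PhantomSpec(12, 12).add_band((2, 10, 2, 10), 135.0)
        gt = generate_phantom(spec)
        fom = compute_fom(simulate_comsli_stack(gt, SCHED))
        counts = fom.n_orientations()
        assert np.all(counts[2:10, 2:10] == 1)
        assert np.all(counts[:2, :] == 0)
        in_band = fom.orientations[2:10, 2:10, 0]
        assert np.all(orientation_separation(in_band, 135.0) < 2.0)

    def test_crossing_phantom_overlap_two_orientations(self):
        gt = fold_phantom(delta_a=0.0, delta_b=90.0)
        fom = compute_fom(simulate_comsli_stack(gt, SCHED))
        overlap = fom.n_orientations()[4:20, 8:16]
        assert np.all(overlap == 2)
        oris = fom.orientations[4:20, 8:16]
        assert np.all(orientation_separation(oris[..., 0], 0.0) < 2.0)
        assert np.all(orientation_separation(oris[..., 1], 90.0) < 2.0)

    def test_three_layers_with_close_pair_merge_to_two(self):
        # two of three layers 20° apart cannot be resolved at 15° sampling
        spec = PhantomSpec(6, 6)
        for d in (0.0, 60.0, 80.0):
            spec.add_band((0, 6, 0, 6), d)
        gt = generate_phantom(spec)
        fom = compute_fom(simulate_comsli_stack(gt, SCHED))
        assert np.all(fom.n_orientations() <= 2)

    def test_rotation_equivariance(self):
        """Cyclically shifting the stack pages rotates every orientation."""
        gt = fold_phantom(width=10, height=10, delta_a=20.0, delta_b=75.0)
        stack = simulate_comsli_stack(gt, SCHED)
        fom = compute_fom(stack)
        shift = 3  # 45°
        rolled = AngularStack(np.roll(stack.intensities, shift, axis=2), SCHED)
        fom_rolled = compute_fom(rolled)
        a = fom.orientations
        b = fom_rolled.orientations
        mask = ~np.isnan(a)
        assert np.array_equal(mask, ~np.isnan(b))
        sep = orientation_separation(b[mask], a[mask] + shift * 15.0)
        assert np.all(sep < 1e-6)


class TestSeparationAndMasking:
    def test_average_map(self):
        stack = AngularStack(np.full((2, 2, 24), 3.0), SCHED)
        assert np.allclose(average_intensity_map(stack), 3.0)
        two = AngularStack(
            np.tile(np.array([0.0, 2.0]), (2, 2, 12)), SCHED
        )
        assert np.allclose(average_intensity_map(two), 1.0)

    def test_peak_distance_in_plane_vs_tilted(self):
        spec = PhantomSpec(8, 8)
        spec.add_band((0, 4, 0, 8), 30.0)  # in-plane rows 0..3
        # rows 4..7 tilted by 30° → separation 180 − 0.5·30 = 165
        spec.add_band((4, 8, 0, 8), 30.0, alpha_deg=30.0)
        gt = generate_phantom(spec)
        fom = compute_fom(simulate_comsli_stack(gt, SCHED))
        dist = peak_distance_map(fom)
        assert np.allclose(dist[:4], 180.0, atol=1.0)
        assert np.allclose(dist[4:], 165.0, atol=1.5)
        assert np.all(dist[4:] < dist[:4])

    def test_mask_fom(self):
        spec = PhantomSpec(10, 10).add_band((0, 10, 0, 5), 45.0)
        gt = generate_phantom(spec)
        stack = simulate_comsli_stack(gt, SCHED)
        fom = compute_fom(stack)
        avg = average_intensity_map(stack)
        # background average is the 5% offset; in-band pixels are brighter
        masked = mask_fom(fom, avg, 0.1)
        assert np.all(masked.n_orientations()[:, :5] >= 1)
        assert np.all(masked.n_orientations()[:, 5:] == 0)
        untouched = mask_fom(fom, avg, 0.0)
        assert np.array_equal(
            untouched.n_orientations(), fom.n_orientations()
        )
        all_gone = mask_fom(fom, avg, avg.max() + 1.0)
        assert np.all(all_gone.n_orientations() == 0)
        with pytest.raises(ValueError):
            mask_fom(fom, avg, -1.0)
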