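"""GrowCut automaton: transition rule, synchronous stepping, convergence.

The key check is exact agreement with a straightforwardly-coded per-pixel
reference simulator of the conquest rule on small random instances.
"""

import numpy as np
import pytest

from segusim import growcut
from segusim.growcut import (LABEL_BACKGROUND, LABEL_FOREGROUND, LABEL_NONE,
                             initialize_state, segment, step,
                             transition_weight)
from segusim.seeds import SeedPoint

OFFSETS = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def reference_fixed_point(image, seeds, max_iters=500):
    """Independent brute-force simulator of the conquest dynamics.

    Plain per-pixel loops over the Moore neighborhood in scan order; the
    strongest strictly-exceeding attacker wins, first in order on ties.
    """
    h, w = image.shape
    labels = np.zeros((h, w), dtype=int)
    theta = np.zeros((h, w))
    hcnt = np.zeros((h, w), dtype=int)
    for s in seeds:
        labels[s.y, s.x] = s.label
        theta[s.y, s.x] = 1.0
    mp = image.max() - image.min()
    for _ in range(max_iters):
        nl, nt = labels.copy(), theta.copy()
        any_change = False
        for y in range(h):
            for x in range(w):
                best = theta[y, x]
                best_lab = None
                for dy, dx in OFFSETS:
                    fy, fx = y + dy, x + dx
                    if not (0 <= fy < h and 0 <= fx < w):
                        continue
                    if labels[fy, fx] == LABEL_NONE:
                        continue
                    g = 1.0 if mp == 0 else max(0.0, min(1.0, 1 - abs(image[y, x] - image[fy, fx]) / mp))
                    attack = theta[fy, fx] * g
                    if attack > best:
                        best = attack
                        best_lab = labels[fy, fx]
                if best_lab is not None:
                    nl[y, x] = best_lab
                    nt[y, x] = best
                    any_change = True
                    if best_lab != labels[y, x]:
                        hcnt[y, x] += 1
        labels, theta = nl, nt
        if not any_change:
            break
    return labels, theta, hcnt


class TestTransitionWeight:
    @pytest.mark.parametrize("ce,cf,mp,expected", [
        (0.4, 0.4, 0.6, 1.0),
        (0.0, 1.0, 1.0, 0.0),
        (0.2, 0.5, 1.0, 0.7),
        (0.3, 0.7, 0.0, 1.0),  # uniform image degenerate case
    ])
    def test_values(self, ce, cf, mp, expected):
        assert transition_weight(ce, cf, mp) == pytest.approx(expected)


class TestStep:
    def test_uniform_image_one_step_conquers_moore_neighbors(self):
        img = np.full((5, 5), 0.5)
        state = initialize_state(img, [SeedPoint(2, 2, LABEL_FOREGROUND)])
        state, changed = step(state)
        assert changed
        expected = np.zeros((5, 5), dtype=bool)
        expected[1:4, 1:4] = True
        np.testing.assert_array_equal(state.labels == LABEL_FOREGROUND, expected)
        assert np.all(state.strengths[1:4, 1:4] == 1.0)

    def test_fixed_point_returned_unchanged(self):
        img = np.full((4, 4), 0.2)
        res = segment(img, [SeedPoint(0, 0, LABEL_BACKGROUND)])
        state = growcut.AutomatonState(res.labels, res.strengths, img,
                                       res.changes, 0.0)
        after, changed = step(state)
        assert not changed
        np.testing.assert_array_equal(after.labels, state.labels)

    def test_seed_is_never_conquered(self, two_region_image, two_region_seeds):
        img, _ = two_region_image
        res = segment(img, two_region_seeds)
        for s in two_region_seeds:
            assert res.labels[s.y, s.x] == s.label
            assert res.strengths[s.y, s.x] == 1.0


class TestSegment:
    def test_two_region_image_recovers_regions(self, two_region_image, two_region_seeds):
        img, gt = two_region_image
        res = segment(img, two_region_seeds)
        assert res.converged
        np.testing.assert_array_equal(res.foreground, gt)

    def test_all_pixels_seeded_is_immediate_fixed_point(self):
        img = np.linspace(0, 1, 12).reshape(3, 4)
        seeds = [SeedPoint(y, x, LABEL_FOREGROUND if (y + x) % 2 else LABEL_BACKGROUND)
                 for y in range(3) for x in range(4)]
        res = segment(img, seeds)
        assert res.converged and res.iterations_run <= 1
        for s in seeds:
            assert res.labels[s.y, s.x] == s.label

    def test_empty_seed_set_rejected(self):
        with pytest.raises(ValueError):
            segment(np.zeros((4, 4)), [])

    def test_border_seed_partition_is_reproducible(self):
        from segusim.seeds import border_background_seeds
        img = np.full((9, 9), 0.4)
        seeds = list(border_background_seeds(img)) + [SeedPoint(4, 4, LABEL_FOREGROUND)]
        a = segment(img, seeds)
        b = segment(img, seeds)
        np.testing.assert_array_equal(a.labels, b.labels)
        np.testing.assert_array_equal(a.changes, b.changes)
        assert set(np.unique(a.labels)) <= {LABEL_BACKGROUND, LABEL_FOREGROUND}


class TestProperties:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_reference_simulator_on_small_instances(self, seed):
        """Synchronous implementation's fixed point equals the brute-force
        per-pixel simulation on random <=7x7 images."""
        rng = np.random.default_rng(seed)
        h, w = rng.integers(3, 8, size=2)
        img = np.round(rng.uniform(size=(h, w)), 2)
        n_seeds = int(rng.integers(1, 4))
        pos = rng.choice(h * w, size=n_seeds, replace=False)
        seeds = [SeedPoint(int(p // w), int(p % w),
                           LABEL_FOREGROUND if rng.uniform() < 0.5 else LABEL_BACKGROUND)
                 for p in pos]
        res = segment(img, seeds)
        ref_labels, ref_theta, ref_h = reference_fixed_point(img, seeds)
        np.testing.assert_array_equal(res.labels, ref_labels)
        np.testing.assert_allclose(res.strengths, ref_theta, atol=1e-12)
        np.testing.assert_array_equal(res.changes, ref_h)

    def test_strengths_bounded_and_monotone(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(size=(10, 10))
        state = initialize_state(img, [SeedPoint(2, 2, LABEL_FOREGROUND),
                                       SeedPoint(7, 7, LABEL_BACKGROUND)])
        prev = state.strengths.copy()
        total_changes = 0
        for _ in range(60):
            state, changed = step(state)
            assert np.all((state.strengths >= 0) & (state.strengths <= 1))
            assert np.all(state.strengths >= prev - 1e-15)
            assert state.changes.sum() >= total_changes
            prev = state.strengths.copy()
            total_changes = state.changes.sum()
            if not changed:
                break
        assert not changed  # termination in finitely many steps

    def test_change_counter_only_where_label_flipped(self, two_region_image, two_region_seeds):
        img, _ = two_region_image
        res = segment(img, two_region_seeds)
        # any cell with h > 0 must carry a definite label now
        assert np.all(res.labels[res.changes > 0] != LABEL_NONE)

    def test_transpose_equivariance(self):
        rng = np.random.default_rng(11)
        img = rng.uniform(size=(6, 9))
        seeds = [SeedPoint(1, 2, LABEL_FOREGROUND), SeedPoint(4, 7, LABEL_BACKGROUND)]
        seeds_t = [SeedPoint(s.x, s.y, s.label) for s in seeds]
        res = segment(img, seeds)
        res_t = segment(img.T, seeds_t)
        np.testing.assert_array_equal(res.labels.T, res_t.labels)
        np.testing.assert_array_equal(res.changes.T, res_t.changes)
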