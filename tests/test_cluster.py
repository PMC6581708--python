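"""Clustering: correlation, modified k-means, GEV, model selection."""

import itertools

import numpy as np
import pytest

import mstates as ms
from mstates.core import TemplateSet, ZeroVarianceError, normalize_maps, spatial_correlation
from mstates.cluster import (
    InsufficientDataError,
    _eigen_template,
    gev_of_assignment,
    group_clustering,
    match_templates,
    modified_kmeans,
    select_k_metacriterion,
)


def _orthonormal_maps(n_ch, n_maps, rng):
    """Random mutually orthogonal zero-mean unit-GFP maps."""
    x = rng.standard_normal((n_ch, n_maps))
    x -= x.mean(axis=0, keepdims=True)  # zero-mean subspace first
    q, _ = np.linalg.qr(x)  # orthogonalizes within that subspace
    return normalize_maps(q.T, canonical=False)


class TestSpatialCorrelation:
    def test_self_is_one(self, rng):
        v = rng.standard_normal(16)
        assert spatial_correlation(v, v) == pytest.approx(1.0)

    def test_polarity_flip(self, rng):
        v = rng.standard_normal(16)
        assert spatial_correlation(v, -v, polarity_invariant=True) == pytest.approx(1.0)
        assert spatial_correlation(v, -v, polarity_invariant=False) == pytest.approx(-1.0)

    def test_orthogonal_centered_maps(self, rng):
        a, b = _orthonormal_maps(16, 2, rng)
        assert spatial_correlation(a, b) == pytest.approx(0.0, abs=1e-10)

    def test_matches_pearson(self, rng):
        from scipy.stats import pearsonr

        a, b = rng.standard_normal((2, 32))
        expected = abs(pearsonr(a, b).statistic)
        assert spatial_correlation(a, b) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ZeroVarianceError):
            spatial_correlation(np.ones(8), np.arange(8.0))


class TestGev:
    def test_perfect_fit_is_one(self, rng):
        maps = _orthonormal_maps(16, 3, rng)
        total, per = gev_of_assignment(maps, maps, np.arange(3))
        assert total == pytest.approx(1.0)
        np.testing.assert_allclose(per.sum(), total)

    def test_orthogonal_templates_explain_nothing(self, rng):
        maps = _orthonormal_maps(16, 4, rng)
        total, _ = gev_of_assignment(maps[:3], maps[3:], np.zeros(3, dtype=int))
        assert total == pytest.approx(0.0, abs=1e-12)

    def test_hand_value(self, rng):
        # correlations {1, 0.5, 0} with equal GFP: (1 + 0.25 + 0) / 3
        base = _orthonormal_maps(16, 3, rng)
        t = base[0]
        m_half = normalize_maps(0.5 * t + np.sqrt(0.75) * base[1], canonical=False)[0]
        maps = np.stack([t, m_half, base[2]])
        total, per = gev_of_assignment(
            maps, t[None, :], np.zeros(3, dtype=int), gfp_weights=np.ones(3)
        )
        assert total == pytest.approx(0.41667, abs=1e-4)


def _brute_force_best_gev(maps, k=2):
    """Exhaustive two-partition optimum.

    Every partition is scored consistently: templates are the dominant
    eigenvectors of the members' amplitude-weighted scatter and the GEV
    is evaluated with that partition as the assignment.  The k-means is
    coordinate ascent on exactly this objective, so with enough restarts
    it must attain the maximum over all partitions.
    """
    from mstates.core import gfp_of_maps

    n = maps.shape[0]
    norm = normalize_maps(maps, canonical=False)
    weighted = norm * gfp_of_maps(maps)[:, None]
    best = -1.0
    for bits in range(1, 2 ** (n - 1)):
        assign = np.array([(bits >> i) & 1 for i in range(n)])
        if assign.min() == assign.max():
            continue
        templates = np.stack(
            [_eigen_template(weighted[assign == c]) for c in range(2)]
        )
        templates = normalize_maps(templates, canonical=False)
        gev, _ = gev_of_assignment(maps, templates, assign)
        best = max(best, gev)
    return best


class TestModifiedKmeans:
    def test_exact_fit_recovers_templates(self, rng):
        t = _orthonormal_maps(16, 2, rng)
        maps = np.vstack([t[0], -t[0], t[1], -t[1], t[0], t[1]])
        res = modified_kmeans(maps, 2, n_restarts=20, seed=0)
        assert res.gev == pytest.approx(1.0)
        _, scores = match_templates(res.templates.maps, t)
        np.testing.assert_allclose(scores, 1.0, atol=1e-9)

    def test_k_equals_distinct_maps_gives_full_gev(self, rng):
        maps = _orthonormal_maps(16, 5, rng)
        res = modified_kmeans(maps, 5, n_restarts=20, seed=0)
        assert res.gev == pytest.approx(1.0)

    def test_matches_exhaustive_partition_oracle(self, rng):
        for _ in range(10):
            maps = rng.standard_normal((7, 16)) * rng.uniform(0.5, 2.0)
            res = modified_kmeans(maps, 2, n_restarts=50, seed=1)
            assert res.gev == pytest.approx(_brute_force_best_gev(maps), abs=1e-9)

    def test_polarity_flip_invariance(self, rng):
        maps = rng.standard_normal((40, 16))
        flips = np.where(rng.random(40) < 0.5, -1.0, 1.0)
        a = modified_kmeans(maps, 3, n_restarts=30, seed=2)
        b = modified_kmeans(maps * flips[:, None], 3, n_restarts=30, seed=2)
        assert a.gev == pytest.approx(b.gev, abs=1e-9)
        _, scores = match_templates(a.templates.maps, b.templates.maps)
        np.testing.assert_allclose(scores, 1.0, atol=1e-8)

    def test_template_rows_normalized(self, rng):
        from mstates.core import gfp_of_maps

        res = modified_kmeans(rng.standard_normal((30, 16)), 4, n_restarts=10, seed=3)
        np.testing.assert_allclose(res.templates.maps.mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(gfp_of_maps(res.templates.maps), 1.0, atol=1e-10)

    def test_gev_nondecreasing_in_k(self, rng):
        maps = rng.standard_normal((60, 16))
        gevs = [
            modified_kmeans(maps, k, n_restarts=30, seed=4).gev for k in range(1, 7)
        ]
        assert all(b >= a - 1e-6 for a, b in zip(gevs, gevs[1:]))

    def test_k_exceeding_maps_rejected(self, rng):
        with pytest.raises(ValueError):
            modified_kmeans(rng.standard_normal((3, 8)), 4)


class TestModelSelection:
    def test_recovers_k_on_separated_clusters(self, rng):
        centers = _orthonormal_maps(16, 4, rng)
        maps = np.repeat(centers, 30, axis=0)
        maps += 0.15 * rng.standard_normal(maps.shape)
        maps *= np.where(rng.random(120) < 0.5, -1.0, 1.0)[:, None]
        sel = select_k_metacriterion(maps, 2, 8, seed=0, n_restarts=20)
        assert sel.chosen_k == 4

    def test_identical_maps_vote_floor(self, rng):
        maps = np.repeat(rng.standard_normal((1, 16)), 12, axis=0)
        sel = select_k_metacriterion(maps, 2, 5, seed=0, n_restarts=5)
        assert sel.chosen_k == 2

    def test_table_has_one_row_per_k(self, rng):
        maps = rng.standard_normal((40, 16))
        sel = select_k_metacriterion(maps, 2, 6, seed=0, n_restarts=10)
        assert list(sel.criterion_table.index) == [2, 3, 4, 5, 6]

    def test_range_shrinks_with_warning(self, rng):
        maps = rng.standard_normal((6, 16))
        with pytest.warns(UserWarning):
            sel = select_k_metacriterion(maps, 2, 10, seed=0, n_restarts=5)
        assert sel.k_range == (2, 5)


class TestTwoStepProcedure:
    def test_individual_clustering_insufficient_peaks(self, montage65, templates4):
        cfg = ms.SimulationConfig(sampling_rate=125.0, duration=2.0, seed=1)
        truth = ms.sample_state_sequence(cfg)
        rec, _ = ms.render_eeg(truth.labels, templates4, cfg, montage65)
        with pytest.raises(InsufficientDataError):
            ms.individual_clustering(rec, k_max=10)

    def test_group_recovers_shared_individual_sets(self, rng):
        shared = _orthonormal_maps(16, 4, rng)
        sets = [TemplateSet(maps=shared.copy()) for _ in range(6)]
        templates, sel = group_clustering(sets, 2, 8, seed=0, n_restarts=10)
        assert sel.chosen_k == 4
        _, scores = match_templates(templates.maps, shared)
        np.testing.assert_allclose(scores, 1.0, atol=1e-9)

    def test_group_subject_order_invariance(self, rng):
        base = _orthonormal_maps(16, 4, rng)
        sets = []
        for i in range(8):
            noisy = base + 0.1 * rng.standard_normal(base.shape)
            sets.append(TemplateSet(maps=normalize_maps(noisy, canonical=False)))
        t1, _ = group_clustering(sets, 2, 6, seed=3, n_restarts=20)
        t2, _ = group_clustering(sets[::-1], 2, 6, seed=3, n_restarts=20)
        _, scores = match_templates(t1.maps, t2.maps)
        assert (scores >= 0.999).all()

    def test_group_requires_two_subjects(self, rng):
        with pytest.raises(ValueError):
            group_clustering([TemplateSet(maps=_orthonormal_maps(16, 4, rng))])

    def test_canonical_reference_naming(self, rng):
        shared = _orthonormal_maps(16, 4, rng)
        sets = [TemplateSet(maps=shared.copy()) for _ in range(4)]
        templates, _ = group_clustering(
            sets, 2, 6, seed=0, n_restarts=10, reference_maps=shared
        )
        assert templates.names is not None
        assert set(templates.names) <= {"A", "B", "C", "D"}
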