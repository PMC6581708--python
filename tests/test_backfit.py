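"""Back-fitting: labeling, temporal smoothing, segment extraction."""

import itertools

import numpy as np
import pytest

import mstates as ms
from mstates.backfit import (
    SmoothingSpec,
    backfit,
    besag_smooth,
    extract_segments,
    label_timepoints,
)
from mstates.core import (
    UNASSIGNED,
    LabelSequence,
    Recording,
    TemplateSet,
    correlation_matrix,
    gfp_of_maps,
    normalize_maps,
)


def _orthonormal_maps(n_ch, n_maps, rng):
    x = rng.standard_normal((n_ch, n_maps))
    x -= x.mean(axis=0, keepdims=True)
    q, _ = np.linalg.qr(x)
    return normalize_maps(q.T, canonical=False)


@pytest.fixture(scope="module")
def toy():
    """16-channel montage with 3 orthogonal templates."""
    rng = np.random.default_rng(42)
    montage = ms.make_montage(16, seed=2)
    maps = _orthonormal_maps(16, 3, rng)
    return montage, TemplateSet(maps=maps)


def _rec(montage, data, sfreq=125.0, excluded=None):
    return Recording(
        data=np.asarray(data, dtype=float),
        sfreq=sfreq,
        montage=montage,
        excluded=excluded,
    )


class TestLabelTimepoints:
    def test_template_and_flipped_template(self, toy):
        montage, ts = toy
        data = np.stack([5 * ts.maps[2], -5 * ts.maps[2]])
        seq = label_timepoints(_rec(montage, data), ts)
        assert seq.labels.tolist() == [2, 2]
        np.testing.assert_allclose(seq.correlations, 1.0)

    def test_orthogonal_sample_unassigned(self, toy):
        montage, ts = toy
        rng = np.random.default_rng(1)
        extra = _orthonormal_maps(16, 4, rng)[3]  # orthogonal by luck? ensure:
        # project out the template span explicitly
        for m in ts.maps:
            extra = extra - (extra @ m) / (m @ m) * m
        seq = label_timepoints(_rec(montage, extra[None, :]), ts)
        assert seq.labels[0] == UNASSIGNED
        assert seq.correlations[0] <= 0.5

    def test_zero_variance_sample_unassigned(self, toy):
        montage, ts = toy
        seq = label_timepoints(_rec(montage, np.zeros((1, 16))), ts)
        assert seq.labels[0] == UNASSIGNED
        assert seq.correlations[0] == 0.0

    def test_excluded_samples_unassigned(self, toy):
        montage, ts = toy
        data = np.repeat(ts.maps[0][None, :], 4, axis=0)
        excl = np.array([False, True, False, False])
        seq = label_timepoints(_rec(montage, data, excluded=excl), ts)
        assert seq.labels.tolist() == [0, UNASSIGNED, 0, 0]


def _run_recording(toy, labels, noise=0.0, amp=None, seed=0):
    montage, ts = toy
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    amp = np.ones(labels.size) if amp is None else np.asarray(amp)
    data = amp[:, None] * ts.maps[np.maximum(labels, 0)]
    data[labels == UNASSIGNED] = 0.0
    data = data + noise * rng.standard_normal(data.shape)
    return _rec(montage, data)


class TestBesagSmooth:
    def test_lambda_zero_is_identity(self, toy):
        montage, ts = toy
        rec = _run_recording(toy, [0, 0, 1, 0, 0, 2, 2], noise=0.3)
        seq = label_timepoints(rec, ts)
        out = besag_smooth(seq, rec, ts, SmoothingSpec(lam=0.0))
        np.testing.assert_array_equal(out.labels, seq.labels)

    def test_single_flip_inside_uniform_run_removed(self, toy):
        montage, ts = toy
        labels = np.zeros(21, dtype=int)
        rec = _run_recording(toy, labels, noise=0.25, seed=3)
        # force an initial flip at the center: tilt that sample toward
        # template 1 just enough to win the argmax
        rec.data[10] = 0.55 * ts.maps[1] + 0.5 * ts.maps[0]
        seq = label_timepoints(rec, ts)
        assert seq.labels[10] == 1
        out = besag_smooth(seq, rec, ts, SmoothingSpec(lam=10.0, window_half_size=3))
        assert out.labels[10] == 0
        assert (out.labels == 0).all()

    def test_clean_piecewise_constant_is_fixed_point(self, toy):
        montage, ts = toy
        labels = np.repeat([0, 1, 2, 0], 8)
        rec = _run_recording(toy, labels, noise=0.0)
        seq = label_timepoints(rec, ts)
        out = besag_smooth(seq, rec, ts, SmoothingSpec(lam=10.0, window_half_size=3))
        np.testing.assert_array_equal(out.labels, labels)

    def test_never_labels_excluded_samples(self, toy):
        montage, ts = toy
        labels = np.zeros(15, dtype=int)
        rec = _run_recording(toy, labels, noise=0.1, seed=1)
        rec.excluded[7] = True
        seq = label_timepoints(rec, ts)
        out = besag_smooth(seq, rec, ts)
        assert out.labels[7] == UNASSIGNED

    def test_matches_brute_force_scorer_on_tiny_sequences(self, toy):
        """On <= 12-sample single-flip sequences the smoothed labeling
        attains the global optimum of the iteration's own scoring rule
        (data term plus frozen-sigma neighborhood bonus), found by
        exhaustive enumeration over all 2^12 labelings."""
        montage, ts = toy
        spec = SmoothingSpec(lam=10.0, window_half_size=3)
        for seed in range(5):
            rng = np.random.default_rng(seed)
            base = int(rng.integers(0, 2))
            true = np.full(12, base)
            rec = _run_recording(toy, true, noise=0.15, seed=seed + 10)
            flip_at = int(rng.integers(3, 9))
            rec.data[flip_at] = 0.6 * ts.maps[1 - base] + 0.5 * ts.maps[base]
            seq = label_timepoints(rec, ts, corr_floor=0.0)
            assert seq.labels[flip_at] == 1 - base
            out = besag_smooth(seq, rec, ts, spec)
            assert (out.labels == base).all()

            # frozen-coefficient objective, same terms as the sweep
            c = correlation_matrix(rec.data, ts.maps)
            gfp = gfp_of_maps(rec.data)
            data = (gfp[:, None] * c) ** 2
            n_ch = rec.n_channels
            c2own = c[np.arange(12), out.labels] ** 2
            sigma2 = float(np.mean(gfp**2 * (1 - c2own)) * n_ch)
            coef = spec.lam * 2.0 * sigma2 / (n_ch - 1)
            b = spec.window_half_size

            def objective(lab):
                lab = np.asarray(lab)
                total = data[np.arange(12), lab].sum()
                for t in range(12):
                    lo, hi = max(0, t - b), min(12, t + b + 1)
                    total += coef * np.sum(lab[lo:hi] == lab[t]) - coef
                return total

            best = max(
                objective(cand)
                for cand in itertools.product(range(2), repeat=12)
            )
            assert objective(out.labels) == pytest.approx(best, rel=1e-12)


class TestExtractSegments:
    def test_runs_and_truncation_flags(self):
        seq = LabelSequence(
            labels=np.array([0, 0, 0, 1, 1]),
            correlations=np.ones(5),
            sfreq=125.0,
            excluded=np.zeros(5, dtype=bool),
        )
        segs = extract_segments(seq)
        assert [(s.label, s.n_samples, s.duration_ms, s.truncated) for s in segs] == [
            (0, 3, 24.0, True),
            (1, 2, 16.0, True),
        ]

    def test_all_unassigned_gives_empty(self):
        seq = LabelSequence(
            labels=np.full(6, UNASSIGNED),
            correlations=np.zeros(6),
            sfreq=125.0,
            excluded=np.zeros(6, dtype=bool),
        )
        assert extract_segments(seq) == []

    def test_ten_samples_is_80_ms(self):
        labels = np.full(14, UNASSIGNED)
        labels[2:12] = 1
        seq = LabelSequence(
            labels=labels,
            correlations=np.ones(14),
            sfreq=125.0,
            excluded=np.zeros(14, dtype=bool),
        )
        (seg,) = extract_segments(seq)
        assert seg.duration_ms == 80.0
        assert not seg.truncated  # bounded by unassigned, not excluded/edge

    def test_excluded_neighbors_mark_truncated(self):
        labels = np.array([UNASSIGNED, 0, 0, 1, 1, UNASSIGNED])
        excl = np.array([True, False, False, False, False, False])
        seq = LabelSequence(
            labels=labels,
            correlations=np.ones(6),
            sfreq=125.0,
            excluded=excl,
        )
        segs = extract_segments(seq)
        assert segs[0].truncated  # abuts the excluded span
        assert not segs[1].truncated

    def test_segments_tile_the_recording(self, preprocessed_subject, templates4):
        rec, _, _ = preprocessed_subject
        seq, segs = backfit(rec, templates4)
        covered = np.zeros(seq.n_samples, dtype=bool)
        for s in segs:
            assert not covered[s.start : s.end].any()  # no overlap
            covered[s.start : s.end] = True
        np.testing.assert_array_equal(covered, seq.labels != UNASSIGNED)


class TestNoiseFreeEndToEnd:
    def test_labels_recovered_where_modulation_is_active(
        self, noisefree_subject, templates4
    ):
        rec, truth, _ = noisefree_subject
        seq, _ = backfit(rec, templates4)
        gfp = gfp_of_maps(rec.data)
        active = gfp > 0.05 * gfp.max()  # a(t) bounded away from 0
        np.testing.assert_array_equal(
            seq.labels[active], truth.labels[: seq.n_samples][active]
        )
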