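"""Synthetic resting-state EEG with known microstate ground truth.

The generator emulates eyes-closed resting EEG as a semi-Markov sequence
of quasi-stable topographies: one of ``K`` smooth dipolar template maps
is active at a time, its amplitude modulated by rectified ~10 Hz
oscillation (alpha dominance), on top of spatially correlated pink
background noise plus white sensor noise, with occasional high-amplitude
frontal transients.  Every recording carries its ground truth (templates,
per-sample labels, dwell times, artifact times) so each downstream stage
of the pipeline can be validated without access to subject data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .core import (
    Montage,
    Recording,
    TemplateSet,
    normalize_maps,
    run_lengths,
    spatial_correlation,
)

#: Sensor-noise standard deviation, microvolts (per channel, pre-SNR scaling).
NOISE_STD_UV = 5.0
#: Power fraction of the spatially correlated pink component of the noise
#: (the remainder is white sensor noise).  Resting EEG background is
#: dominated by a few smooth cortical generators, so most noise power is
#: spatially structured.
CORRELATED_NOISE_FRACTION = 0.7
#: Spatial length scale (chord units on the unit sphere) of the noise
#: correlation kernel.
NOISE_LENGTH_SCALE = 0.6
#: Maximum pairwise |spatial correlation| allowed between generated templates.
TEMPLATE_MAX_CORR = 0.7


class GenerationError(RuntimeError):
    """Raised when a valid template set cannot be generated."""


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions of one synthetic subject.

    Defaults mirror the acquisition this generator emulates: a
    65-channel geodesic net sampled at 500 Hz, eyes-closed runs of a few
    minutes, states dwelling ~80 ms with gamma-distributed durations,
    alpha (10 Hz) amplitude modulation, and template-to-noise power
    ratio 4.
    """

    n_channels: int = 65
    n_classes: int = 4
    sampling_rate: float = 500.0
    duration: float = 180.0  # seconds
    dwell_mean: float = 80.0  # ms
    dwell_shape: float = 4.0  # gamma shape
    carrier_freq: float = 10.0  # Hz
    snr: float = 4.0  # template power / noise power
    artifact_rate: float = 2.0  # events per minute
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_channels",
            "n_classes",
            "sampling_rate",
            "duration",
            "dwell_mean",
            "dwell_shape",
            "carrier_freq",
            "snr",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.artifact_rate < 0:
            raise ValueError("artifact_rate must be >= 0")
        if self.n_classes < 2:
            raise ValueError("need at least 2 microstate classes")
        if self.dwell_mean / 1000.0 * self.sampling_rate < 2:
            raise ValueError("mean dwell must span at least 2 samples")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))


@dataclass
class GroundTruth:
    """What the generator actually produced, for validation."""

    templates: TemplateSet
    labels: np.ndarray  # per-sample true class, 0..K-1
    dwell_times_ms: list[float]
    artifact_samples: list[int] = field(default_factory=list)
    config: SimulationConfig | None = None

    def decimated_labels(self, factor: int) -> np.ndarray:
        """Ground-truth labels aligned with a factor-``q`` decimated signal."""
        return self.labels[::factor]


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


# ---------------------------------------------------------------------------
# montage and templates


def make_montage(n_channels: int, seed: int = 0) -> Montage:
    """Quasi-uniform electrode layout on the upper unit hemisphere.

    A Fibonacci lattice covers the hemisphere; the seed applies a random
    azimuthal rotation so distinct seeds give distinct (but equally
    uniform) layouts.  Deterministic for a given ``(n_channels, seed)``.
    """
    if n_channels < 2:
        raise ValueError("a montage needs at least 2 channels")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 101]))
    phi0 = rng.uniform(0, 2 * np.pi)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    i = np.arange(n_channels)
    # z from just above the equator to the vertex, uniform in area
    z = (i + 0.5) / n_channels
    theta = golden * i + phi0
    r = np.sqrt(1.0 - z**2)
    pos = np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)
    names = tuple(f"E{k + 1}" for k in range(n_channels))
    return Montage(channel_names=names, positions=pos)


def _dipole_map(montage: Montage, rng: np.random.Generator) -> np.ndarray:
    """Scalp field of one randomly placed/oriented dipole pair.

    Point-dipole potential in a homogeneous medium, evaluated at the
    electrodes; smooth by construction, which is what makes spatial
    smoothing and spatial correlation meaningful on synthetic data.
    """
    pos = montage.positions
    field_sum = np.zeros(montage.n_channels)
    for _ in range(2):
        center = rng.normal(size=3)
        center = 0.55 * center / np.linalg.norm(center)
        center[2] = abs(center[2]) * 0.6  # keep sources inside the upper head
        moment = rng.normal(size=3)
        moment /= np.linalg.norm(moment)
        d = pos - center
        dist = np.linalg.norm(d, axis=1)
        field_sum += (d @ moment) / dist**3
    return field_sum


def make_templates(
    montage: Montage,
    k: int,
    seed: int = 0,
    max_corr: float = TEMPLATE_MAX_CORR,
    max_retries: int = 500,
) -> TemplateSet:
    """Generate K smooth, mutually distinct template maps.

    Each map is average-referenced, unit-GFP, canonical-sign, and the
    pairwise |spatial correlation| between any two maps is at most
    ``max_corr`` (rejection sampling; :class:`GenerationError` if the
    bound cannot be met).
    """
    if k < 2:
        raise ValueError("need at least 2 templates")
    if k > montage.n_channels - 1:
        raise ValueError("k must be at most n_channels - 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 202]))
    maps: list[np.ndarray] = []
    tries = 0
    while len(maps) < k:
        cand = normalize_maps(_dipole_map(montage, rng))[0]
        if all(spatial_correlation(cand, m) <= max_corr for m in maps):
            maps.append(cand)
        else:
            tries += 1
            if tries > max_retries:
                raise GenerationError(
                    f"could not draw {k} maps with pairwise |r| <= {max_corr}"
                )
    return TemplateSet(maps=np.stack(maps), level="group")


# ---------------------------------------------------------------------------
# state sequence


def sample_state_sequence(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> GroundTruth:
    """Semi-Markov microstate sequence covering the whole recording.

    The next class is drawn uniformly among the other classes; dwell
    times are gamma(shape, mean/shape) milliseconds, rounded to at least
    one sample.  Returned dwell times are the realized run lengths in ms
    (the final run is cut at the recording edge).
    """
    rng = rng if rng is not None else _rng(config, 303)
    n = config.n_samples
    fs = config.sampling_rate
    k = config.n_classes
    scale = config.dwell_mean / config.dwell_shape
    labels = np.empty(n, dtype=int)
    t = 0
    current = int(rng.integers(k))
    while t < n:
        dwell_ms = rng.gamma(config.dwell_shape, scale)
        n_samp = max(1, int(round(dwell_ms / 1000.0 * fs)))
        labels[t : t + n_samp] = current
        t += n_samp
        if k == 2:
            current = 1 - current
        else:
            step = int(rng.integers(k - 1))
            current = step if step < current else step + 1
    dwell = [(e - s) * 1000.0 / fs for _, s, e in run_lengths(labels)]
    return GroundTruth(templates=None, labels=labels, dwell_times_ms=dwell, config=config)


# ---------------------------------------------------------------------------
# noise and rendering


def _pink_noise(n: int, n_ch: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise, independent per channel."""
    white = rng.standard_normal((n, n_ch))
    spec = np.fft.rfft(white, axis=0)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    spec *= shaping[:, None]
    out = np.fft.irfft(spec, n=n, axis=0)
    out /= out.std(axis=0, keepdims=True)
    return out


def _noise_mixing(montage: Montage) -> np.ndarray:
    """Spatial mixing matrix from electrode distances (Gaussian kernel)."""
    d = montage.distances()
    k = np.exp(-(d**2) / (2.0 * NOISE_LENGTH_SCALE**2))
    k += 1e-6 * np.eye(montage.n_channels)
    return np.linalg.cholesky(k)


def make_noise(
    config: SimulationConfig, montage: Montage, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Background noise: spatially correlated pink + white sensor noise.

    Per-channel standard deviation is :data:`NOISE_STD_UV` microvolts,
    with :data:`CORRELATED_NOISE_FRACTION` of the power in the smooth
    correlated component.
    """
    rng = rng if rng is not None else _rng(config, 404)
    n, n_ch = config.n_samples, config.n_channels
    pink = _pink_noise(n, n_ch, config.sampling_rate, rng) @ _noise_mixing(montage).T
    pink /= pink.std(axis=0, keepdims=True)
    white = rng.standard_normal((n, n_ch))
    mix = np.sqrt(CORRELATED_NOISE_FRACTION) * pink + np.sqrt(
        1.0 - CORRELATED_NOISE_FRACTION
    ) * white
    return NOISE_STD_UV * mix


def render_eeg(
    labels: np.ndarray,
    templates: TemplateSet,
    config: SimulationConfig,
    montage: Montage,
    noise_scale: float = 1.0,
) -> tuple[Recording, GroundTruth]:
    """Turn a label sequence into a multichannel recording.

    ``signal(t) = s_seg * A_seg * |sin(2 pi f t + phi_seg)| * T[label(t)]
    + noise(t)`` where the per-segment amplitude ``A_seg`` is set so
    that segment-mean template power / noise power equals ``config.snr``,
    ``phi_seg`` is a per-segment random phase and ``s_seg`` a random
    polarity sign (exercising polarity invariance end-to-end).

    ``noise_scale`` scales the noise amplitude (0 gives the noise-free
    limit used by validity checks).
    """
    labels = np.asarray(labels, dtype=int)
    if labels.max() >= templates.n_templates or labels.min() < 0:
        raise ValueError("labels and templates are inconsistent")
    rng = _rng(config, 505)
    n = labels.shape[0]
    fs = config.sampling_rate
    t = np.arange(n) / fs
    amp = np.zeros(n)
    sign = np.zeros(n)
    for _, s, e in run_lengths(labels):
        phi = rng.uniform(0, 2 * np.pi)
        a = np.abs(np.sin(2 * np.pi * config.carrier_freq * t[s:e] + phi))
        # segment-mean template power / noise power = snr; very short
        # segments caught at an oscillation node get a floored mean so the
        # amplitude stays finite
        mean_a2 = max(float(np.mean(a**2)), 0.02)
        scale = NOISE_STD_UV * np.sqrt(config.snr / mean_a2)
        amp[s:e] = scale * a
        sign[s:e] = rng.choice([-1.0, 1.0])
    signal = (sign * amp)[:, None] * templates.maps[labels]
    noise = make_noise(config, montage) if noise_scale != 0 else 0.0
    data = signal + noise_scale * noise
    rec = Recording(data=data, sfreq=fs, montage=montage, reference="average")
    truth = GroundTruth(
        templates=templates,
        labels=labels,
        dwell_times_ms=[(e - s) * 1000.0 / fs for _, s, e in run_lengths(labels)],
        config=config,
    )
    return rec, truth


def inject_artifacts(
    rec: Recording,
    config: SimulationConfig,
    truth: GroundTruth | None = None,
) -> Recording:
    """Add transient frontal-weighted deflections exceeding 150 uV.

    Event times are Poisson with ``config.artifact_rate`` per minute;
    each event is a ~0.3 s Gaussian bump peaking at 200 uV on the most
    frontal channels.  Peak sample indices are appended to
    ``truth.artifact_samples`` so the rejection stage can be validated.
    """
    if config.artifact_rate == 0:
        return rec.copy_with(data=rec.data.copy())
    rng = _rng(config, 606)
    n = rec.n_samples
    n_events = rng.poisson(config.artifact_rate / 60.0 * rec.duration_s)
    data = rec.data.copy()
    # frontal weighting: electrodes toward +y on the unit sphere
    y = rec.montage.positions[:, 1]
    w = np.clip((y - y.min()) / (y.max() - y.min()), 0.0, 1.0) ** 2
    width = 0.05 * rec.sfreq  # ~50 ms std
    times = []
    for _ in range(n_events):
        c = int(rng.integers(n))
        lo, hi = max(0, c - int(4 * width)), min(n, c + int(4 * width))
        bump = 200.0 * np.exp(-0.5 * ((np.arange(lo, hi) - c) / width) ** 2)
        data[lo:hi] += rng.choice([-1.0, 1.0]) * bump[:, None] * w[None, :]
        times.append(c)
    if truth is not None:
        truth.artifact_samples.extend(sorted(times))
    return rec.copy_with(data=data)


# ---------------------------------------------------------------------------
# convenience drivers


def simulate_subject(
    config: SimulationConfig,
    montage: Montage | None = None,
    templates: TemplateSet | None = None,
    with_artifacts: bool = True,
) -> tuple[Recording, GroundTruth]:
    """One synthetic subject end to end.

    Montage and templates may be shared across a cohort (real microstate
    classes are common across humans); when omitted they are derived
    from ``config.seed``.
    """
    if montage is None:
        montage = make_montage(config.n_channels, seed=config.seed)
    if templates is None:
        templates = make_templates(montage, config.n_classes, seed=config.seed)
    truth = sample_state_sequence(config)
    rec, truth = render_eeg(truth.labels, templates, config, montage)
    if with_artifacts:
        rec = inject_artifacts(rec, config, truth)
    return rec, truth


def simulate_cohort(
    n_group_a: int,
    n_group_b: int,
    base_config: SimulationConfig,
    seed: int | None = None,
) -> tuple[Montage, TemplateSet, list[tuple[str, str, Recording, GroundTruth]]]:
    """A two-group cohort sharing one montage and one true template set.

    Subjects differ only in their per-subject random streams (state
    sequence, noise, artifacts); group labels are ``"A"``/``"B"``.
    Returns ``(montage, templates, [(subject_id, group, rec, truth)])``.
    """
    seed = base_config.seed if seed is None else int(seed)
    montage = make_montage(base_config.n_channels, seed=seed)
    templates = make_templates(montage, base_config.n_classes, seed=seed)
    subjects = []
    for idx in range(n_group_a + n_group_b):
        group = "A" if idx < n_group_a else "B"
        sid = f"sub-{idx + 1:02d}"
        cfg = dataclasses.replace(base_config, seed=int((seed * 1000 + idx) % 2**31))
        rec, truth = simulate_subject(cfg, montage=montage, templates=templates)
        subjects.append((sid, group, rec, truth))
    return montage, templates, subjects
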