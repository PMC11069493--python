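"""Ground-truth source activity, synthetic EEG epochs, and a two-class
motor-imagery dataset.

The localization benchmark activates, per epoch, one "main" source inside the
hand-knob regions of interest and two weaker background sources elsewhere.
Each time course is a Gaussian-windowed sinusoid

    x_i(t) = a_i * exp(-((t - c_i)/sigma_i)^2 / 2) * sin(2 pi f_i t),

projected to the scalp through the lead field (y = M x) and optionally
degraded with additive white Gaussian noise at a nominal SNR.

The motor-imagery generator emulates the physiology a left/right-hand BCI
exploits: ongoing mu-rhythm (10 Hz) activity in both hand-knob ROIs whose
amplitude drops in the hemisphere *contralateral* to the imagined hand after
the cue (event-related desynchronization), on top of broadband background
sources and sensor noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .headmodel import LeadField, SourceSpace

__all__ = [
    "RoiSpec",
    "SourceEvent",
    "EpochSet",
    "SimConfig",
    "MiConfig",
    "default_hand_knob_markers",
    "select_roi",
    "gauss_sine",
    "simulate_epochs",
    "add_noise",
    "empirical_snr_db",
    "simulate_mi_dataset",
]


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class RoiSpec:
    """Seed markers (one per hemisphere) and the neighbourhood size k."""

    markers: np.ndarray  # (2, 3) meters
    k: int = 20

    def __post_init__(self):
        m = np.asarray(self.markers, float).reshape(2, 3)
        object.__setattr__(self, "markers", m)
        if self.k < 0:
            raise ValueError("k must be non-negative")
        if m[0, 0] * m[1, 0] >= 0:
            raise ValueError("markers must lie on opposite hemispheres")


@dataclass(frozen=True)
class SourceEvent:
    """One Gaussian-windowed sinusoid: amplitude, center (s), width (s), frequency (Hz)."""

    source_index: int
    amplitude: float = 1.0
    center: float = 1.0
    width: float = 0.12
    frequency: float = 10.0

    def __post_init__(self):
        if self.amplitude < 0 or self.width <= 0 or self.frequency <= 0:
            raise ValueError("require amplitude >= 0, width > 0, frequency > 0")


@dataclass
class EpochSet:
    """Trials x channels x samples with per-trial ground truth.

    ``truth`` holds the main-source index (localization datasets) or the class
    label (classification datasets) of each trial.
    """

    data: np.ndarray
    sfreq: float
    truth: np.ndarray
    snr_db: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_channels, n_samples)")
        self.truth = np.asarray(self.truth)
        if len(self.truth) != self.data.shape[0]:
            raise ValueError("truth length must equal n_trials")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sfreq

    def times(self, start: float = 0.0) -> np.ndarray:
        return start + np.arange(self.n_samples) / self.sfreq


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the localization benchmark.

    Two 2-second epochs per ROI source at 250 Hz; the main source is a 10 Hz
    Gaussian-windowed sinusoid (width 0.12 s) centered at 1 s; two background
    sources at 10% of the main amplitude, widths 0.12 s, frequencies 5 and
    20 Hz, drawn uniformly from sources at least 3 cm from the main source
    (and outside the ROI).
    """

    duration: float = 2.0
    sfreq: float = 250.0
    epochs_per_source: int = 2
    main_amplitude: float = 1.0
    main_frequency: float = 10.0
    main_width: float = 0.12
    main_center: float = 1.0
    background_ratio: float = 0.10
    background_frequencies: tuple[float, ...] = (5.0, 20.0)
    background_width: float = 0.12
    background_min_dist: float = 0.03


def default_hand_knob_markers(cortex_radius: float = 0.078) -> np.ndarray:
    """Stand-in hand-knob seed points: the scalp directions of C3/C4 (the
    electrodes classically overlying the hand motor cortex) scaled to the
    cortical shell."""
    direction = np.array([np.sin(np.deg2rad(36.0)), 0.0, np.cos(np.deg2rad(36.0))])
    left = cortex_radius * direction * np.array([-1.0, 1.0, 1.0])
    right = cortex_radius * direction
    return np.vstack([left, right])


def select_roi(src: SourceSpace, roi: RoiSpec) -> np.ndarray:
    """Indices of the k Euclidean-nearest sources to each marker (union).

    Equals the brute-force full distance sort; duplicates (a source nearest to
    both markers) are collapsed.
    """
    if roi.k > src.n_per_hemisphere:
        raise ValueError("k exceeds the number of sources per hemisphere")
    shell_radius = float(np.linalg.norm(src.positions[0]))
    picked: list[int] = []
    for marker in roi.markers:
        off_shell = abs(np.linalg.norm(marker) - shell_radius)
        if off_shell > shell_radius:
            raise ValueError("ROI marker lies too far off the cortical shell")
        d = np.linalg.norm(src.positions - marker[None, :], axis=1)
        order = np.argsort(d, kind="stable")
        picked.extend(order[: roi.k].tolist())
    return np.unique(np.asarray(picked, dtype=int))


def gauss_sine(event: SourceEvent, t: np.ndarray) -> np.ndarray:
    """Evaluate the Gaussian-windowed sinusoid on the sample grid ``t``."""
    t = np.asarray(t, float)
    envelope = event.amplitude * np.exp(-0.5 * ((t - event.center) / event.width) ** 2)
    return envelope * np.sin(2.0 * np.pi * event.frequency * t)


@dataclass(frozen=True)
class TrialTruth:
    """Sparse ground truth of one trial: active sources and their time courses."""

    main_index: int
    background_indices: tuple[int, int]
    time_courses: np.ndarray  # (3, n_samples), row 0 = main

    @property
    def active_indices(self) -> np.ndarray:
        return np.array([self.main_index, *self.background_indices], dtype=int)


def simulate_epochs(
    lf: LeadField,
    roi_indices,
    cfg: SimConfig = SimConfig(),
    seed: int = 0,
    background: bool = True,
) -> tuple[EpochSet, list[TrialTruth]]:
    """Noiseless EEG epochs (y = M x, eps = 0) for the localization benchmark.

    ``epochs_per_source`` epochs are generated per ROI source; each activates
    that source plus (unless ``background=False``) two interfering sources.
    Per-trial randomness (background locations) derives from ``seed`` through
    a spawned-stream counter, so the set is bit-reproducible.
    """
    roi_indices = np.asarray(roi_indices, int)
    if roi_indices.size == 0:
        raise SimulationError("empty ROI")
    n_samples = int(round(cfg.duration * cfg.sfreq))
    t = np.arange(n_samples) / cfg.sfreq
    pos = lf.source_space.positions

    n_trials = cfg.epochs_per_source * roi_indices.size
    data = np.empty((n_trials, lf.n_channels, n_samples))
    truth_idx = np.empty(n_trials, dtype=int)
    truths: list[TrialTruth] = []
    streams = np.random.SeedSequence(seed).spawn(n_trials)

    trial = 0
    for s_main in roi_indices:
        for _ in range(cfg.epochs_per_source):
            rng = np.random.default_rng(streams[trial])
            main = SourceEvent(
                int(s_main),
                cfg.main_amplitude,
                cfg.main_center,
                cfg.main_width,
                cfg.main_frequency,
            )
            events = [main]
            if background:
                dist = np.linalg.norm(pos - pos[s_main][None, :], axis=1)
                eligible = np.flatnonzero(dist >= cfg.background_min_dist)
                eligible = eligible[~np.isin(eligible, roi_indices)]
                if eligible.size < len(cfg.background_frequencies):
                    raise SimulationError(
                        "no eligible background locations at the required distance"
                    )
                bg = rng.choice(eligible, size=len(cfg.background_frequencies), replace=False)
                for b, f in zip(bg, cfg.background_frequencies):
                    events.append(
                        SourceEvent(
                            int(b),
                            cfg.background_ratio * cfg.main_amplitude,
                            cfg.main_center,
                            cfg.background_width,
                            f,
                        )
                    )
            x = np.vstack([gauss_sine(ev, t) for ev in events])
            idx = np.array([ev.source_index for ev in events])
            data[trial] = lf.gain[:, idx] @ x
            truth_idx[trial] = s_main
            bg_pair = tuple(int(i) for i in idx[1:]) if background else (-1, -1)
            truths.append(TrialTruth(int(s_main), bg_pair, x))
            trial += 1

    epochs = EpochSet(
        data,
        cfg.sfreq,
        truth_idx,
        snr_db=None,
        meta={"seed": seed, "kind": "localization", "background": background},
    )
    return epochs, truths


def add_noise(
    epochs: EpochSet, snr_db: float | None, seed: int = 0, per_trial: bool = False
) -> EpochSet:
    """Additive white Gaussian sensor noise at a nominal SNR (dB).

    The noise variance is set so that 10*log10(P_signal/P_noise) equals
    ``snr_db`` with powers averaged over the whole epoch set (or per trial
    with ``per_trial=True``).  ``snr_db=None`` returns the input unchanged.
    """
    if snr_db is None:
        return epochs
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    factor = 10.0 ** (snr_db / 10.0)
    if per_trial:
        p_sig = np.mean(epochs.data**2, axis=(1, 2), keepdims=True)
    else:
        p_sig = np.mean(epochs.data**2)
    sd = np.sqrt(p_sig / factor)
    noise = sd * rng.standard_normal(epochs.data.shape)
    meta = dict(epochs.meta, noise_seed=seed, per_trial_snr=per_trial)
    return EpochSet(epochs.data + noise, epochs.sfreq, epochs.truth.copy(), snr_db, meta)


def empirical_snr_db(clean: EpochSet | np.ndarray, noisy: EpochSet | np.ndarray) -> float:
    """Recomputed 10*log10(P_signal/P_noise) between a clean set and its noisy version."""
    c = np.asarray(getattr(clean, "data", clean), float)
    n = np.asarray(getattr(noisy, "data", noisy), float)
    noise = n - c
    return float(10.0 * np.log10(np.mean(c**2) / np.mean(noise**2)))


@dataclass(frozen=True)
class MiConfig:
    """Study conditions of the synthetic motor-imagery dataset.

    Epochs span -1 s to +3 s around the cue at 250 Hz; 60 trials per class.
    Both hand-knob ROIs carry ongoing 10 Hz mu activity; after the cue the ROI
    contralateral to the imagined hand is attenuated by ``erd_depth`` (0.5 =
    50% amplitude drop).  Broadband activity in randomly drawn non-ROI
    sources and white sensor noise complete the generative model.
    """

    tmin: float = -1.0
    tmax: float = 3.0
    sfreq: float = 250.0
    n_trials_per_class: int = 60
    erd_depth: float = 0.5
    mu_frequency: float = 10.0
    mu_amplitude: float = 1.0
    amplitude_jitter: float = 0.1
    erd_ramp: float = 0.1  # seconds, cue-onset transition
    n_background_sources: int = 100
    background_amplitude: float = 0.3
    sensor_snr_db: float = 10.0

    def __post_init__(self):
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ValueError("erd_depth must lie in [0, 1]")
        if self.tmin >= self.tmax:
            raise ValueError("epoch window must have tmin < tmax")


def simulate_mi_dataset(
    lf: LeadField,
    roi_left,
    roi_right,
    cfg: MiConfig = MiConfig(),
    seed: int = 0,
) -> EpochSet:
    """Two-class (left=0 / right=1 hand) motor-imagery EpochSet.

    Imagining the LEFT hand desynchronizes the RIGHT-hemisphere hand knob and
    vice versa.  Labels are balanced and trial order is shuffled; the
    generator is bit-reproducible for a fixed seed.
    """
    roi_left = np.asarray(roi_left, int)
    roi_right = np.asarray(roi_right, int)
    n_samples = int(round((cfg.tmax - cfg.tmin) * cfg.sfreq))
    t = cfg.tmin + np.arange(n_samples) / cfg.sfreq
    n_trials = 2 * cfg.n_trials_per_class
    labels = np.array([0] * cfg.n_trials_per_class + [1] * cfg.n_trials_per_class)
    master = np.random.default_rng(np.random.SeedSequence(seed))
    labels = labels[master.permutation(n_trials)]
    streams = np.random.SeedSequence(seed).spawn(n_trials + 1)

    # smooth ERD gate: 1 before the cue, (1 - depth) after, erd_ramp transition
    gate = np.ones_like(t)
    post = t >= 0
    ramp = np.clip(t / max(cfg.erd_ramp, 1.0 / cfg.sfreq), 0.0, 1.0)
    gate[post] = 1.0 - cfg.erd_depth * ramp[post]

    roi_all = set(roi_left.tolist()) | set(roi_right.tolist())
    non_roi = np.array([i for i in range(lf.n_sources) if i not in roi_all])

    data = np.empty((n_trials, lf.n_channels, n_samples))
    for trial in range(n_trials):
        rng = np.random.default_rng(streams[trial])
        contralateral = roi_right if labels[trial] == 0 else roi_left
        ipsi = roi_left if labels[trial] == 0 else roi_right
        y = np.zeros((lf.n_channels, n_samples))
        for roi, gated in ((contralateral, True), (ipsi, False)):
            # mu generators within one hand knob oscillate coherently: a common
            # per-trial phase with small per-source jitter (local synchrony is
            # what the "(de)synchronization" terminology refers to)
            phases = rng.uniform(0, 2 * np.pi) + 0.2 * rng.standard_normal(roi.size)
            amps = cfg.mu_amplitude * np.exp(
                cfg.amplitude_jitter * rng.standard_normal(roi.size)
            )
            mu = amps[:, None] * np.sin(
                2 * np.pi * cfg.mu_frequency * t[None, :] + phases[:, None]
            )
            if gated:
                mu = mu * gate[None, :]
            y += lf.gain[:, roi] @ mu
        if cfg.n_background_sources > 0 and non_roi.size > 0:
            k = min(cfg.n_background_sources, non_roi.size)
            bg = rng.choice(non_roi, size=k, replace=False)
            courses = cfg.background_amplitude * rng.standard_normal((k, n_samples))
            y += lf.gain[:, bg] @ courses
        data[trial] = y

    epochs = EpochSet(
        data,
        cfg.sfreq,
        labels,
        snr_db=None,
        meta={"seed": seed, "kind": "motor_imagery", "tmin": cfg.tmin, "tmax": cfg.tmax},
    )
    if cfg.sensor_snr_db is not None:
        noise_rng_seed = streams[n_trials].generate_state(1)[0] % (2**31)
        epochs = add_noise(epochs, cfg.sensor_snr_db, seed=int(noise_rng_seed))
        epochs.meta.update(kind="motor_imagery", tmin=cfg.tmin, tmax=cfg.tmax)
    return epochs
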