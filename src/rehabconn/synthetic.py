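"""Synthetic EEG cohort with a planted pre/post connectivity change.

Each virtual subject contributes two sessions ("before"/"after") per task.
A session is synthesized as a continuous multichannel recording with event
markers and then pushed through the real preprocessing chain, so the
pipeline is exercised end to end:

    sensors = mixing_kernel @ (band-limited latent oscillators, some of
              them coupled) * osc_sd + 1/f background + white sensor noise

The latent oscillators are band-limited Gaussian noise (FIR-filtered white
noise), not sinusoids, so instantaneous phase is nondegenerate.  Volume
conduction is emulated by instantaneous Gaussian spatial mixing over the
electrode montage -- exactly the zero-lag spread that wPLI and iCPCC are
built to reject.  The planted effect changes the coupling strength of a
known set of channel pairs between sessions, through one of three
mechanisms:

* ``phase_coupling``      - the target's band latent partially follows the
  source's with a fixed phase lag (raises PLV/CPCC, and wPLI for lag != 0);
* ``directed_var``        - the source's past is injected linearly into the
  target (raises Granger causality source -> target);
* ``amplitude_dependence``- the target's envelope partially follows the
  source's (raises envelope mutual information).

Per-subject variability is a log-normal multiplicative jitter on the
coupling strengths, drawn once per subject.  Everything is deterministic
given the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from .preprocessing import (
    ContinuousEEG,
    EpochedEEG,
    FilterSpec,
    PreprocessConfig,
    design_windowed_sinc,
    filter_zero_phase,
    preprocess,
)
from .connectivity import BandSpec, get_band

MECHANISMS = ("phase_coupling", "directed_var", "amplitude_dependence")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class CouplingEffect:
    """The planted connectivity contrast between sessions."""

    target_pairs: tuple[tuple[int, int], ...] = ((0, 8), (3, 11), (6, 14))
    band: str = "low_gamma"
    mechanism: str = "phase_coupling"
    strength_pre: float = 0.1
    strength_post: float = 0.9
    phase_lag: float = math.pi / 4

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        for s in (self.strength_pre, self.strength_post):
            if not (0.0 <= s <= 1.0):
                raise ValueError("coupling strengths must lie in [0, 1]")

    @property
    def band_spec(self) -> BandSpec:
        return get_band(self.band)


@dataclass
class NoiseSpec:
    one_over_f_exponent: float = 1.0
    sensor_noise_sd: float = 2.0  # uV
    background_sd: float = 6.0  # uV, 1/f process
    mixing_spread: float = 0.35  # radians of great-circle angle; 0 = no mixing

    def __post_init__(self) -> None:
        if self.sensor_noise_sd < 0 or self.background_sd < 0:
            raise ValueError("noise SDs must be non-negative")


@dataclass
class CohortConfig:
    n_subjects: int = 8
    n_channels: int = 16
    sampling_rate: float = 500.0
    n_trials_per_session: int = 80
    trial_layout: tuple[float, float, float] = (500.0, 1200.0, 800.0)  # ms
    tasks: tuple[str, ...] = ("verbal",)
    effect: CouplingEffect = field(default_factory=CouplingEffect)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    subject_jitter_sd: float = 0.15  # log-normal sigma on coupling strengths
    oscillator_sd: float = 4.0  # uV per band-limited latent, post-mixing scale
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.n_trials_per_session < 1:
            raise ValueError("need at least 1 trial per session")
        band = self.effect.band_spec
        if self.sampling_rate <= 2 * band.high_hz:
            raise ValueError("sampling rate must exceed twice the band's top edge")
        for i, j in self.effect.target_pairs:
            if not (0 <= i < self.n_channels and 0 <= j < self.n_channels) or i == j:
                raise ValueError(f"invalid target pair ({i}, {j}) for {self.n_channels} channels")


@dataclass
class SubjectParams:
    subject_id: str
    strength_pre: float
    strength_post: float


@dataclass
class GroundTruth:
    """What was planted: the answer key for feature-recovery checks."""

    target_pairs: tuple[tuple[int, int], ...]
    mechanism: str
    band: str
    strength_pre: float
    strength_post: float
    phase_lag: float
    subject_strengths: dict[str, tuple[float, float]]

    def to_dict(self) -> dict:
        return {
            "target_pairs": [list(p) for p in self.target_pairs],
            "mechanism": self.mechanism,
            "band": self.band,
            "strength_pre": self.strength_pre,
            "strength_post": self.strength_post,
            "phase_lag": self.phase_lag,
            "subject_strengths": {k: list(v) for k, v in self.subject_strengths.items()},
        }


# ---------------------------------------------------------------------------
# montage and mixing
# ---------------------------------------------------------------------------

def synthetic_montage(n_channels: int) -> tuple[list[str], np.ndarray]:
    """Fibonacci-lattice electrode positions on the upper unit hemisphere."""
    golden = (1 + math.sqrt(5)) / 2
    k = np.arange(n_channels)
    z = 0.15 + (0.95 - 0.15) * (k + 0.5) / n_channels  # stay off the equator/vertex
    r = np.sqrt(1 - z**2)
    theta = 2 * math.pi * k / golden
    pos = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    names = [f"CH{c:03d}" for c in range(n_channels)]
    return names, pos


def mixing_kernel(positions: np.ndarray, spread: float) -> np.ndarray:
    """Instantaneous volume-conduction mixing: Gaussian in great-circle angle.

    Rows are normalized to unit sum; ``spread <= 0`` returns the identity
    (no mixing).
    """
    n = positions.shape[0]
    if spread <= 0:
        return np.eye(n)
    cosang = np.clip(positions @ positions.T, -1.0, 1.0)
    ang = np.arccos(cosang)
    m = np.exp(-(ang**2) / (2 * spread**2))
    return m / m.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# signal building blocks
# ---------------------------------------------------------------------------

def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def _band_noise(rng: np.random.Generator, n: int, fs: float, band: BandSpec) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise (windowed-sinc filtered)."""
    order = min(int(round(3.0 * fs / band.low_hz / 2.0)) * 2, 3000, (n - 2) // 2 * 2)
    taps = design_windowed_sinc(
        FilterSpec("band_pass", order, (band.low_hz, min(band.high_hz, fs / 2 * 0.999)), fs)
    )
    return _standardize(filter_zero_phase(rng.standard_normal(n), taps))


def _one_over_f(rng: np.random.Generator, n: int, fs: float, exponent: float) -> np.ndarray:
    """Unit-variance 1/f^exponent background noise via spectral shaping."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spectrum = rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))
    with np.errstate(divide="ignore"):
        shape = np.where(freqs > 0, freqs ** (-exponent / 2.0), 0.0)
    return _standardize(np.fft.irfft(spectrum * shape, n=n))


def _phase_lagged(x: np.ndarray, lag_rad: float) -> np.ndarray:
    """Copy of a narrowband signal with a constant phase lag (via Hilbert)."""
    return np.real(hilbert(x) * np.exp(-1j * lag_rad))


def _couple(latents: np.ndarray, effect: CouplingEffect, strength: float,
            fs: float) -> np.ndarray:
    """Impose the planted coupling on the target channels' latents."""
    out = latents.copy()
    s = float(np.clip(strength, 0.0, 1.0))
    mix = math.sqrt(max(1.0 - s**2, 0.0))
    for i, j in effect.target_pairs:
        src = latents[i]
        if effect.mechanism == "phase_coupling":
            drive = _phase_lagged(src, effect.phase_lag)
        elif effect.mechanism == "directed_var":
            d = max(int(round(fs * 0.004)), 1)  # ~4 ms axonal-style delay
            drive = np.zeros_like(src)
            drive[d:] = src[:-d]
        else:  # amplitude_dependence: shared envelope, own carrier phase
            env = np.abs(hilbert(src))
            tgt_analytic = hilbert(latents[j])
            carrier = np.cos(np.angle(tgt_analytic))
            drive = env * carrier
        out[j] = mix * latents[j] + s * _standardize(drive)
    return out


# ---------------------------------------------------------------------------
# session and cohort synthesis
# ---------------------------------------------------------------------------

def simulate_continuous(
    params: SubjectParams,
    session: str,
    task: str,
    cfg: CohortConfig,
    rng: np.random.Generator,
) -> ContinuousEEG:
    """One continuous session recording with per-trial event markers."""
    fs = cfg.sampling_rate
    stim_ms, maint_ms, rest_ms = cfg.trial_layout
    trial_samples = int(round((stim_ms + maint_ms + rest_ms) * fs / 1000.0))
    lead = int(round(fs))  # 1 s of padding at each end
    n = 2 * lead + cfg.n_trials_per_session * trial_samples
    names, pos = synthetic_montage(cfg.n_channels)

    band = cfg.effect.band_spec
    latents = np.stack([_band_noise(rng, n, fs, band) for _ in range(cfg.n_channels)])
    strength = params.strength_pre if session == "before" else params.strength_post
    latents = _couple(latents, cfg.effect, strength, fs)

    m = mixing_kernel(pos, cfg.noise.mixing_spread)
    x = cfg.oscillator_sd * (m @ latents)
    if cfg.noise.background_sd > 0:
        x += cfg.noise.background_sd * np.stack(
            [_one_over_f(rng, n, fs, cfg.noise.one_over_f_exponent)
             for _ in range(cfg.n_channels)]
        )
    if cfg.noise.sensor_noise_sd > 0:
        x += cfg.noise.sensor_noise_sd * rng.standard_normal((cfg.n_channels, n))

    stim_samples = int(round(stim_ms * fs / 1000.0))
    events = [(lead + k * trial_samples + stim_samples, task)
              for k in range(cfg.n_trials_per_session)]
    return ContinuousEEG(samples=x, sampling_rate=fs, channel_names=names,
                         channel_positions=pos, events=events)


def simulate_session(
    params: SubjectParams,
    session: str,
    task: str,
    cfg: CohortConfig,
    rng: np.random.Generator,
    preprocess_cfg: PreprocessConfig | None = None,
) -> EpochedEEG:
    """Synthesize a session and run it through the real preprocessing path."""
    cont = simulate_continuous(params, session, task, cfg, rng)
    if preprocess_cfg is None:
        preprocess_cfg = PreprocessConfig.default(cfg.sampling_rate)
    return preprocess(cont, preprocess_cfg, subject_id=params.subject_id,
                      session=session, task=task)


def subject_parameters(cfg: CohortConfig) -> list[SubjectParams]:
    """Per-subject coupling strengths: log-normal jitter, drawn once each."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xC0F0]))
    out = []
    for s in range(cfg.n_subjects):
        jitter = float(np.exp(rng.normal(0.0, cfg.subject_jitter_sd)))
        out.append(SubjectParams(
            subject_id=f"S{s:02d}",
            strength_pre=float(np.clip(cfg.effect.strength_pre * jitter, 0.0, 1.0)),
            strength_post=float(np.clip(cfg.effect.strength_post * jitter, 0.0, 1.0)),
        ))
    return out


def make_cohort(
    cfg: CohortConfig,
    preprocess_cfg: PreprocessConfig | None = None,
) -> tuple[list[EpochedEEG], GroundTruth]:
    """Generate the full cohort: one EpochedEEG per subject x session x task.

    Deterministic given ``cfg.seed``; the returned GroundTruth lists exactly
    the channel pairs whose coupling differs between sessions (all target
    pairs when the pre/post strengths differ, none otherwise).
    """
    subjects = subject_parameters(cfg)
    recordings = []
    for si, params in enumerate(subjects):
        for sess_i, session in enumerate(("before", "after")):
            for ti, task in enumerate(cfg.tasks):
                rng = np.random.default_rng(
                    np.random.SeedSequence([cfg.seed, 1 + si, sess_i, ti])
                )
                recordings.append(
                    simulate_session(params, session, task, cfg, rng, preprocess_cfg)
                )
    truth = GroundTruth(
        target_pairs=cfg.effect.target_pairs,
        mechanism=cfg.effect.mechanism,
        band=cfg.effect.band,
        strength_pre=cfg.effect.strength_pre,
        strength_post=cfg.effect.strength_post,
        phase_lag=cfg.effect.phase_lag,
        subject_strengths={p.subject_id: (p.strength_pre, p.strength_post)
                           for p in subjects},
    )
    return recordings, truth
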