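"""Continuous-EEG preprocessing: FIR filtering, epoching, artifact handling.

The pipeline implemented here mirrors a conventional event-related EEG
cleaning chain: line-noise band-stop and broadband band-pass filtering with
Hamming-windowed sinc FIR filters applied in a single zero-phase pass,
extraction of event-locked epochs (1100 ms, 100 ms pre-stimulus baseline),
automatic bad-channel detection (5 SD rule on per-channel activity),
baseline removal, +/-50 uV epoch rejection, common-average re-referencing,
and spherical-spline interpolation of removed channels.

All voltages are in microvolts, all times in milliseconds relative to the
time-locking event.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.signal import fftconvolve, freqz

logger = logging.getLogger(__name__)

SESSIONS = ("before", "after")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ContinuousEEG:
    """A continuous multichannel recording with event markers.

    samples : (n_channels, n_samples) float array, microvolts
    channel_positions : (n_channels, 3) unit-sphere electrode coordinates
    events : list of (sample_index, label)
    """

    samples: np.ndarray
    sampling_rate: float
    channel_names: list[str]
    channel_positions: np.ndarray
    events: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be (n_channels, n_samples)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("non-finite sample values")
        self.channel_positions = np.asarray(self.channel_positions, dtype=float)
        if self.channel_positions.shape != (self.n_channels, 3):
            raise ValueError("channel_positions must be (n_channels, 3)")
        norms = np.linalg.norm(self.channel_positions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("channel positions must lie on the unit sphere")
        for s, _ in self.events:
            if not (0 <= s < self.n_samples):
                raise ValueError(f"event sample {s} outside record")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


@dataclass
class FilterSpec:
    """Hamming-windowed sinc FIR filter specification.

    ``cutoffs_hz`` are the -6 dB points; the realized transition width of the
    Hamming design is about ``3.3 * fs / order`` Hz.
    """

    kind: str  # "band_stop" | "band_pass"
    order: int
    cutoffs_hz: tuple[float, float]
    sampling_rate: float
    transition_hz: float | None = None
    window: str = "hamming"

    def __post_init__(self) -> None:
        if self.kind not in ("band_stop", "band_pass"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.order % 2 != 0:
            raise ValueError("filter order must be even (type-I linear phase)")
        low, high = self.cutoffs_hz
        if not (0 < low < high < self.sampling_rate / 2):
            raise ValueError("cutoffs must satisfy 0 < low < high < Nyquist")
        if self.window != "hamming":
            raise ValueError("only the Hamming window is supported")


@dataclass
class EpochedEEG:
    """Event-locked epochs: ``data`` is (n_epochs, n_channels, n_samples)."""

    data: np.ndarray
    t0_offset_ms: float
    sampling_rate: float
    channel_names: list[str]
    channel_positions: np.ndarray
    subject_id: str = ""
    session: str = ""
    task: str = ""
    kept_epoch_indices: np.ndarray | None = None
    bad_channels: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_epochs, n_channels, n_samples)")
        if self.kept_epoch_indices is None:
            self.kept_epoch_indices = np.arange(self.data.shape[0])
        self.kept_epoch_indices = np.asarray(self.kept_epoch_indices, dtype=int)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times in ms relative to the event."""
        return self.t0_offset_ms + 1000.0 * np.arange(self.n_samples) / self.sampling_rate


# ---------------------------------------------------------------------------
# FIR design and zero-phase filtering
# ---------------------------------------------------------------------------

def _lowpass_kernel(order: int, cutoff_hz: float, fs: float) -> np.ndarray:
    """DC-normalized Hamming-windowed sinc low-pass prototype (-6 dB at cutoff)."""
    n = np.arange(order + 1) - order / 2
    h = 2.0 * cutoff_hz / fs * np.sinc(2.0 * cutoff_hz / fs * n)
    h *= np.hamming(order + 1)
    return h / h.sum()


def _spectral_invert(h: np.ndarray) -> np.ndarray:
    g = -h.copy()
    g[len(h) // 2] += 1.0
    return g


def design_windowed_sinc(spec: FilterSpec) -> np.ndarray:
    """Return the order+1 symmetric taps of a Hamming-windowed sinc filter.

    The band-stop is built as low-pass(low) + spectral inversion of
    low-pass(high); the band-pass is the spectral complement of that
    band-stop.  Both are type-I linear-phase kernels with unity DC (band-stop)
    or unity mid-band (band-pass) gain to within the window's ripple.
    """
    low, high = spec.cutoffs_hz
    band_stop = _lowpass_kernel(spec.order, low, spec.sampling_rate) + _spectral_invert(
        _lowpass_kernel(spec.order, high, spec.sampling_rate)
    )
    if spec.kind == "band_stop":
        return band_stop
    return _spectral_invert(band_stop)


def frequency_response(taps: np.ndarray, fs: float, n_points: int = 1 << 16):
    """Magnitude response |H(f)| of the taps on a dense frequency grid."""
    w, h = freqz(taps, worN=n_points, fs=fs)
    return w, np.abs(h)


def filter_zero_phase(signal, taps: np.ndarray):
    """One-pass zero-phase FIR filtering with group-delay compensation.

    The signal is reflect-padded by order/2 at both ends and convolved once
    with the symmetric taps; taking the 'valid' part of the convolution
    compensates the integer group delay, so no net phase shift remains at any
    frequency.  Accepts a raw array (filtering along the last axis),
    a ContinuousEEG, or an EpochedEEG; returns the same type.
    """
    taps = np.asarray(taps, dtype=float)
    if len(taps) % 2 != 1:
        raise ValueError("taps must have odd length (even order)")
    if not np.allclose(taps, taps[::-1], atol=1e-12):
        raise ValueError("taps must be symmetric (linear phase)")
    if isinstance(signal, ContinuousEEG):
        return replace(signal, samples=filter_zero_phase(signal.samples, taps))
    if isinstance(signal, EpochedEEG):
        return replace(signal, data=filter_zero_phase(signal.data, taps))
    x = np.asarray(signal, dtype=float)
    half = (len(taps) - 1) // 2
    if x.shape[-1] <= len(taps) - 1:
        raise ValueError(
            f"signal length {x.shape[-1]} not greater than filter order {len(taps) - 1}"
        )
    pad = [(0, 0)] * (x.ndim - 1) + [(half, half)]
    xp = np.pad(x, pad, mode="reflect")
    shape = [1] * (x.ndim - 1) + [len(taps)]
    return fftconvolve(xp, taps.reshape(shape), mode="valid", axes=-1)


# ---------------------------------------------------------------------------
# epoching and artifact handling
# ---------------------------------------------------------------------------

def extract_epochs(
    cont: ContinuousEEG,
    window_ms: tuple[float, float] = (-100.0, 1000.0),
    subject_id: str = "",
    session: str = "",
    task: str = "",
) -> EpochedEEG:
    """Cut event-locked epochs out of a continuous recording.

    The epoch spans ``window_ms`` around each event; events whose window runs
    past the record edges are dropped with a warning.
    """
    if not cont.events:
        raise ValueError("no events to epoch around")
    fs = cont.sampling_rate
    n0 = int(round(window_ms[0] * fs / 1000.0))
    n1 = int(round(window_ms[1] * fs / 1000.0))
    if n1 <= n0:
        raise ValueError("empty epoch window")
    epochs, kept = [], []
    for k, (s, _label) in enumerate(cont.events):
        lo, hi = s + n0, s + n1
        if lo < 0 or hi > cont.n_samples:
            logger.warning("event %d at sample %d clipped by record edge; dropped", k, s)
            continue
        epochs.append(cont.samples[:, lo:hi])
        kept.append(k)
    if not epochs:
        raise ValueError("all events clipped by record edges")
    return EpochedEEG(
        data=np.stack(epochs),
        t0_offset_ms=window_ms[0],
        sampling_rate=fs,
        channel_names=list(cont.channel_names),
        channel_positions=cont.channel_positions,
        subject_id=subject_id,
        session=session,
        task=task,
        kept_epoch_indices=np.asarray(kept),
    )


def detect_bad_channels(ep: EpochedEEG, z_threshold: float = 5.0) -> list[int]:
    """Flag channels whose activity deviates > ``z_threshold`` SD from the rest.

    Activity is the per-channel standard deviation pooled over all epochs and
    samples; each channel is z-scored against the leave-self-out mean/SD of
    the other channels' activities, so a single extreme channel cannot mask
    itself.
    """
    if ep.n_channels < 3:
        raise ValueError("need at least 3 channels for bad-channel detection")
    activity = ep.data.std(axis=(0, 2))
    bad = []
    for c in range(ep.n_channels):
        others = np.delete(activity, c)
        sd = others.std(ddof=1)
        if sd == 0:
            continue
        z = (activity[c] - others.mean()) / sd
        if abs(z) > z_threshold:
            bad.append(c)
    return bad


def baseline_correct(ep: EpochedEEG) -> EpochedEEG:
    """Subtract the mean of the pre-stimulus interval per epoch and channel."""
    t = ep.times_ms
    base = (t >= -100.0) & (t < 0.0)
    if not base.any():
        raise ValueError("epoch window does not include the [-100, 0) ms baseline")
    means = ep.data[:, :, base].mean(axis=2, keepdims=True)
    return replace(ep, data=ep.data - means)


def reject_epochs(ep: EpochedEEG, amp_threshold_uv: float = 50.0) -> EpochedEEG:
    """Drop epochs exceeding +/- ``amp_threshold_uv`` at any channel/sample."""
    peak = np.abs(ep.data).max(axis=(1, 2))
    keep = peak <= amp_threshold_uv
    if not keep.any():
        raise ValueError(
            f"all {ep.n_epochs} epochs exceed +/-{amp_threshold_uv} uV "
            f"(min peak {peak.min():.1f} uV); check scaling/baseline"
        )
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("rejected %d/%d epochs above %.1f uV", n_drop, ep.n_epochs, amp_threshold_uv)
    return replace(
        ep,
        data=ep.data[keep],
        kept_epoch_indices=ep.kept_epoch_indices[keep],
    )


def rereference_average(ep: EpochedEEG, exclude: Sequence[int] = ()) -> EpochedEEG:
    """Common-average re-referencing.

    The across-channel mean (over channels not in ``exclude``) is subtracted
    from every channel at every time point.  With no exclusions the
    across-channel mean of the output is exactly zero.
    """
    if ep.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    include = np.setdiff1d(np.arange(ep.n_channels), np.asarray(exclude, dtype=int))
    if include.size < 2:
        raise ValueError("fewer than 2 channels left to reference against")
    mean = ep.data[:, include, :].mean(axis=1, keepdims=True)
    return replace(ep, data=ep.data - mean)


# ---------------------------------------------------------------------------
# spherical-spline interpolation
# ---------------------------------------------------------------------------

def _g_matrix(cosang: np.ndarray, m: int, n_terms: int) -> np.ndarray:
    """Spherical-spline kernel g(cos angle) as a truncated Legendre series."""
    x = np.clip(cosang, -1.0, 1.0)
    # Legendre recurrence P_0..P_{n_terms}
    p_prev = np.ones_like(x)
    p = x.copy()
    out = np.zeros_like(x)
    for n in range(1, n_terms + 1):
        out += (2 * n + 1) / (float(n) ** m * float(n + 1) ** m) * p
        p_next = ((2 * n + 1) * x * p - n * p_prev) / (n + 1)
        p_prev, p = p, p_next
    return out / (4.0 * np.pi)


def interpolate_spherical(
    ep: EpochedEEG,
    bad: Sequence[int],
    m: int = 4,
    n_terms: int = 50,
    reg: float = 1e-5,
) -> EpochedEEG:
    """Replace bad channels by spherical-spline estimates from the good ones.

    Fits a spline on the unit sphere through the good channels at every time
    point (Legendre-series kernel of order ``m`` truncated at ``n_terms``
    terms, diagonal regularization ``reg``) and evaluates it at the bad
    electrode positions.  Good channels pass through unchanged.
    """
    bad = sorted(set(int(b) for b in bad))
    if not bad:
        return ep
    if any(b < 0 or b >= ep.n_channels for b in bad):
        raise ValueError("bad channel index out of range")
    good = [c for c in range(ep.n_channels) if c not in bad]
    if len(good) < 4:
        raise ValueError("spherical-spline interpolation needs >= 4 good channels")
    pos = ep.channel_positions
    cos_gg = pos[good] @ pos[good].T
    cos_bg = pos[bad] @ pos[good].T
    g_gg = _g_matrix(cos_gg, m, n_terms) + reg * np.eye(len(good))
    g_bg = _g_matrix(cos_bg, m, n_terms)
    # spline system with the constant term: [[G, 1], [1^T, 0]] [c; d] = [v; 0]
    n_good = len(good)
    a = np.zeros((n_good + 1, n_good + 1))
    a[:n_good, :n_good] = g_gg
    a[:n_good, n_good] = 1.0
    a[n_good, :n_good] = 1.0
    v = ep.data[:, good, :].transpose(1, 0, 2).reshape(n_good, -1)
    rhs = np.vstack([v, np.zeros((1, v.shape[1]))])
    sol = np.linalg.solve(a, rhs)
    coef, const = sol[:n_good], sol[n_good]
    est = g_bg @ coef + const  # (n_bad, n_epochs*n_samples)
    data = ep.data.copy()
    data[:, bad, :] = est.reshape(len(bad), ep.n_epochs, ep.n_samples).transpose(1, 0, 2)
    return replace(ep, data=data)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

@dataclass
class PreprocessConfig:
    """Thresholds and filter orders for the standard cleaning chain."""

    notch: FilterSpec | None = None
    band_pass: FilterSpec | None = None
    window_ms: tuple[float, float] = (-100.0, 1000.0)
    z_threshold: float = 5.0
    amp_threshold_uv: float = 50.0
    epoch_transform: Callable[[EpochedEEG], EpochedEEG] | None = None
    """Pluggable hook standing in for manual ICA-based artifact removal."""

    @staticmethod
    def default(sampling_rate: float = 500.0) -> "PreprocessConfig":
        return PreprocessConfig(
            notch=FilterSpec("band_stop", 990, (48.0, 52.0), sampling_rate, transition_hz=2.0),
            band_pass=FilterSpec("band_pass", 1650, (1.0, 70.0), sampling_rate, transition_hz=1.0),
        )


def preprocess(
    cont: ContinuousEEG,
    cfg: PreprocessConfig | None = None,
    subject_id: str = "",
    session: str = "",
    task: str = "",
) -> EpochedEEG:
    """Run the full fixed-order cleaning chain on a continuous recording.

    Order: notch -> band-pass -> epoch -> bad-channel detection ->
    (epoch-transform hook) -> baseline -> epoch rejection -> average
    reference (computed over good channels) -> spherical interpolation of
    the bad channels.
    """
    if cfg is None:
        cfg = PreprocessConfig.default(cont.sampling_rate)
    x = cont
    if cfg.notch is not None:
        x = filter_zero_phase(x, design_windowed_sinc(cfg.notch))
    if cfg.band_pass is not None:
        x = filter_zero_phase(x, design_windowed_sinc(cfg.band_pass))
    ep = extract_epochs(x, cfg.window_ms, subject_id=subject_id, session=session, task=task)
    bad = detect_bad_channels(ep, cfg.z_threshold)
    if bad:
        logger.info("subject %s %s: bad channels %s", subject_id, session, bad)
    if cfg.epoch_transform is not None:
        ep = cfg.epoch_transform(ep)
    ep = baseline_correct(ep)
    ep = reject_epochs(ep, cfg.amp_threshold_uv)
    ep = rereference_average(ep, exclude=bad)
    ep = interpolate_spherical(ep, bad)
    return replace(ep, bad_channels=bad)
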