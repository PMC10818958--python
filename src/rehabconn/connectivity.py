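"""Per-epoch functional and effective connectivity estimation.

Five estimators over band-limited analytic signals (Hilbert transform of
zero-phase FIR band-passed epochs) or broadband real signals:

* PLV  - phase-locking value: modulus of the mean unit phasor of the phase
  difference; 1 means a perfectly constant phase difference.
* wPLI - weighted phase-lag index: uses only the imaginary cross-spectrum,
  so zero-lag (volume-conducted) coupling contributes nothing.
* CPCC - complex Pearson correlation coefficient: normalized complex inner
  product of the analytic signals; absCPCC = modulus (total coupling),
  iCPCC = imaginary part (lagged coupling only).
* MI   - mutual information of the instantaneous amplitude envelopes,
  plug-in histogram estimate in bits.
* GC   - Granger causality: log ratio of univariate to bivariate
  autoregressive prediction-error variances, on broadband real signals.

Canonical frequency bands: delta 0.5-4 Hz, theta 4-7 Hz, low gamma
30-45 Hz, high gamma 45-60 Hz; GC uses the full 1-70 Hz broadband.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from .preprocessing import EpochedEEG, FilterSpec, design_windowed_sinc, filter_zero_phase

logger = logging.getLogger(__name__)

UNDIRECTED_MEASURES = ("plv", "wpli", "cpcc", "abs_cpcc", "i_cpcc", "mi")
DIRECTED_MEASURES = ("gc",)
MEASURES = UNDIRECTED_MEASURES + DIRECTED_MEASURES


@dataclass(frozen=True)
class BandSpec:
    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError("band edges must satisfy 0 < low < high")


BANDS = {
    "delta": BandSpec("delta", 0.5, 4.0),
    "theta": BandSpec("theta", 4.0, 7.0),
    "low_gamma": BandSpec("low_gamma", 30.0, 45.0),
    "high_gamma": BandSpec("high_gamma", 45.0, 60.0),
    "broadband": BandSpec("broadband", 1.0, 70.0),
}


def get_band(band) -> BandSpec:
    if isinstance(band, BandSpec):
        return band
    try:
        return BANDS[band]
    except KeyError:
        raise ValueError(f"unknown band {band!r}; known: {sorted(BANDS)}") from None


# ---------------------------------------------------------------------------
# analytic signals
# ---------------------------------------------------------------------------

@dataclass
class AnalyticEpoch:
    """Complex analytic signals of one epoch: ``x`` is (n_channels, n_samples).

    ``edge_mask`` flags the 10% taper region at each end where Hilbert edge
    effects distort phase/amplitude; estimators can optionally exclude it.
    """

    x: np.ndarray
    band: BandSpec
    sampling_rate: float
    edge_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=complex)
        if self.edge_mask is None:
            n = self.x.shape[-1]
            k = int(round(0.1 * n))
            mask = np.zeros(n, dtype=bool)
            mask[:k] = True
            if k:
                mask[-k:] = True
            self.edge_mask = mask

    @property
    def n_samples(self) -> int:
        return self.x.shape[-1]

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.x)

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.x)


def _band_filter_taps(band: BandSpec, fs: float, n_samples: int) -> np.ndarray:
    """Band-pass taps for analytic-signal extraction.

    Order is 3 * fs / low_hz rounded to even, capped at n_samples - 2 so the
    zero-phase reflect padding stays shorter than the epoch.
    """
    order = int(round(3.0 * fs / band.low_hz / 2.0)) * 2
    cap = (n_samples - 2) // 2 * 2
    order = min(order, cap)
    if order < 6:
        raise ValueError("epoch too short for band filtering")
    high = min(band.high_hz, fs / 2 * 0.999)
    spec = FilterSpec("band_pass", order, (band.low_hz, high), fs)
    return design_windowed_sinc(spec)


def _analytic_stack(ep: EpochedEEG, band: BandSpec) -> np.ndarray:
    """Band-pass + Hilbert transform of all epochs: (n_epochs, n_ch, n_samp) complex."""
    fs = ep.sampling_rate
    if band.high_hz > fs / 2:
        raise ValueError(f"band {band.name} exceeds Nyquist ({fs / 2} Hz)")
    center = 0.5 * (band.low_hz + band.high_hz)
    if ep.n_samples / fs < 2.0 / center:
        raise ValueError(
            f"epoch of {ep.n_samples / fs:.3f} s too short for band {band.name} "
            f"(< 2 cycles of {center:.2f} Hz)"
        )
    if band.low_hz < 48.0 < band.high_hz or band.low_hz < 52.0 < band.high_hz:
        logger.warning(
            "band %s overlaps the 48-52 Hz line-noise stop band; "
            "content there was removed by the notch filter", band.name,
        )
    taps = _band_filter_taps(band, fs, ep.n_samples)
    filtered = filter_zero_phase(ep.data, taps)
    return hilbert(filtered, axis=-1)


def analytic_band(ep: EpochedEEG, band) -> list[AnalyticEpoch]:
    """Band-limited analytic signals, one :class:`AnalyticEpoch` per epoch."""
    band = get_band(band)
    stack = _analytic_stack(ep, band)
    return [AnalyticEpoch(x=stack[e], band=band, sampling_rate=ep.sampling_rate)
            for e in range(stack.shape[0])]


def _pair_signals(a: AnalyticEpoch, i: int, j: int, exclude_edges: bool):
    xi, xj = a.x[i], a.x[j]
    if exclude_edges:
        keep = ~a.edge_mask
        xi, xj = xi[keep], xj[keep]
    return xi, xj


# ---------------------------------------------------------------------------
# scalar estimators
# ---------------------------------------------------------------------------

def plv(a: AnalyticEpoch, i: int, j: int, exclude_edges: bool = False) -> float:
    """Phase-locking value |mean(exp(1j * (phi_i - phi_j)))| in [0, 1]."""
    xi, xj = _pair_signals(a, i, j, exclude_edges)
    zero = (np.abs(xi) == 0) | (np.abs(xj) == 0)
    if zero.any():
        logger.warning("zero-amplitude samples in PLV; their phase taken as 0")
    phi = np.where(np.abs(xi) == 0, 0.0, np.angle(xi)) - np.where(
        np.abs(xj) == 0, 0.0, np.angle(xj)
    )
    return float(np.abs(np.mean(np.exp(1j * phi))))


def wpli(a: AnalyticEpoch, i: int, j: int, exclude_edges: bool = False) -> float:
    """Weighted phase-lag index; defined as 0 when the cross-spectrum is purely real."""
    xi, xj = _pair_signals(a, i, j, exclude_edges)
    im = np.imag(xi * np.conj(xj))
    den = np.sum(np.abs(im))
    # purely real cross-spectrum up to rounding: no lagged coupling
    if den <= 1e-12 * np.sum(np.abs(xi) * np.abs(xj)):
        return 0.0
    return float(np.abs(np.sum(im)) / den)


def cpcc(a: AnalyticEpoch, i: int, j: int, exclude_edges: bool = False) -> complex:
    """Complex Pearson correlation coefficient; |result| <= 1."""
    xi, xj = _pair_signals(a, i, j, exclude_edges)
    e1 = np.sum(np.abs(xi) ** 2)
    e2 = np.sum(np.abs(xj) ** 2)
    if e1 == 0 or e2 == 0:
        raise ValueError("zero-energy channel in CPCC")
    return complex(np.sum(xi * np.conj(xj)) / np.sqrt(e1 * e2))


def abs_cpcc(a: AnalyticEpoch, i: int, j: int, **kw) -> float:
    return abs(cpcc(a, i, j, **kw))


def i_cpcc(a: AnalyticEpoch, i: int, j: int, **kw) -> float:
    return cpcc(a, i, j, **kw).imag


def _mi_bins(n: int) -> int:
    return int(math.ceil(math.sqrt(n / 5.0)))


def _constant(a: np.ndarray) -> bool:
    return np.ptp(a) <= 1e-12 * max(np.abs(a).max(), 1e-300)


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def mutual_information(a: AnalyticEpoch, i: int, j: int, exclude_edges: bool = False) -> float:
    """Plug-in histogram MI of the amplitude envelopes, in bits.

    Equal-width bins, ceil(sqrt(N/5)) per axis over each channel's amplitude
    range.  A constant envelope on either channel gives MI = 0.
    """
    xi, xj = _pair_signals(a, i, j, exclude_edges)
    ai, aj = np.abs(xi), np.abs(xj)
    if ai.size < 64:
        raise ValueError("MI needs at least 64 samples")
    if _constant(ai) or _constant(aj):
        return 0.0
    nb = _mi_bins(ai.size)
    joint, _, _ = np.histogram2d(ai, aj, bins=nb)
    h_x = _entropy(joint.sum(axis=1))
    h_y = _entropy(joint.sum(axis=0))
    h_xy = _entropy(joint)
    return max(h_x + h_y - h_xy, 0.0)


def amplitude_entropy(a: AnalyticEpoch, i: int, exclude_edges: bool = False) -> float:
    """Marginal plug-in entropy of one channel's envelope (the MI diagonal)."""
    xi, _ = _pair_signals(a, i, i, exclude_edges)
    ai = np.abs(xi)
    if _constant(ai):
        return 0.0
    counts, _ = np.histogram(ai, bins=_mi_bins(ai.size))
    return _entropy(counts)


def _lagged(x: np.ndarray, order: int) -> np.ndarray:
    """(order, N-order) matrix of lagged copies: row l-1 is x[t-l]."""
    n = x.size
    return np.stack([x[order - l : n - l] for l in range(1, order + 1)])


def _ols_rss(design: np.ndarray, y: np.ndarray) -> float:
    """Residual sum of squares of y on design rows (no intercept)."""
    beta, res, rank, _ = np.linalg.lstsq(design.T, y, rcond=None)
    if rank < design.shape[0]:
        raise np.linalg.LinAlgError("rank-deficient autoregressive design")
    return float(np.sum((y - design.T @ beta) ** 2))


def granger(x: np.ndarray, y: np.ndarray, order: int = 5) -> tuple[float, float]:
    """Pairwise Granger causality (gc_xy, gc_yx) from broadband real signals.

    gc_xy = log(Var(e_y) / Var(e_y|x,y)): the reduction in the target's
    prediction-error variance when the source's past is added to an AR(order)
    model fitted by ordinary least squares on the de-meaned epoch.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("signals must have equal length")
    if x.size < 10 * order:
        raise ValueError(f"epoch length {x.size} < 10 * order {order}")
    x = x - x.mean()
    y = y - y.mean()
    lx, ly = _lagged(x, order), _lagged(y, order)
    out = []
    for src_l, tgt, tgt_l in ((lx, y[order:], ly), (ly, x[order:], lx)):
        rss_uni = _ols_rss(tgt_l, tgt)
        rss_biv = _ols_rss(np.vstack([tgt_l, src_l]), tgt)
        out.append(max(math.log(rss_uni / max(rss_biv, 1e-300)), 0.0))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# connectivity tensors
# ---------------------------------------------------------------------------

@dataclass
class ConnectivityTensor:
    """Per-epoch channel x channel matrices for one measure and band.

    Diagonal conventions: PLV/absCPCC 1, wPLI/iCPCC 0, CPCC 1+0j,
    MI the marginal envelope entropy, GC 0.
    """

    values: np.ndarray  # (n_epochs, C, C)
    measure: str
    band: BandSpec
    directed: bool
    complex_valued: bool
    subject_id: str = ""
    session: str = ""
    task: str = ""

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


def _plv_matrices(stack: np.ndarray) -> np.ndarray:
    amp = np.abs(stack)
    z = np.where(amp == 0, 1.0 + 0j, stack / np.where(amp == 0, 1.0, amp))
    m = np.abs(np.einsum("ecs,eds->ecd", z, np.conj(z))) / stack.shape[-1]
    for e in range(m.shape[0]):
        np.fill_diagonal(m[e], 1.0)
    return m


def _wpli_matrices(stack: np.ndarray) -> np.ndarray:
    e_, c, s = stack.shape
    out = np.empty((e_, c, c))
    for e in range(e_):
        cross = np.einsum("cs,ds->cds", stack[e], np.conj(stack[e])).imag
        num = np.abs(cross.sum(axis=-1))
        den = np.abs(cross).sum(axis=-1)
        amp = np.abs(stack[e])
        scale = amp @ amp.T
        ok = den > 1e-12 * scale
        out[e] = np.where(ok, num / np.where(ok, den, 1.0), 0.0)
        np.fill_diagonal(out[e], 0.0)
    return out


def _cpcc_matrices(stack: np.ndarray) -> np.ndarray:
    inner = np.einsum("ecs,eds->ecd", stack, np.conj(stack))
    energy = np.einsum("ecc->ec", inner).real
    if np.any(energy == 0):
        raise ValueError("zero-energy channel in CPCC")
    norm = np.sqrt(energy[:, :, None] * energy[:, None, :])
    m = inner / norm
    for e in range(m.shape[0]):
        np.fill_diagonal(m[e], 1.0 + 0j)
    return m


def _mi_matrices(epochs: list[AnalyticEpoch], exclude_edges: bool) -> np.ndarray:
    c = epochs[0].x.shape[0]
    out = np.zeros((len(epochs), c, c))
    for e, a in enumerate(epochs):
        for i in range(c):
            out[e, i, i] = amplitude_entropy(a, i, exclude_edges=exclude_edges)
            for j in range(i + 1, c):
                v = mutual_information(a, i, j, exclude_edges=exclude_edges)
                out[e, i, j] = out[e, j, i] = v
    return out


def _gc_matrices(data: np.ndarray, order: int) -> np.ndarray:
    """GC for every ordered channel pair of every epoch, via normal equations.

    data : (n_epochs, C, S) broadband real signals.  Entry [e, i, j] is the
    causality from source i to target j; the diagonal is 0.
    """
    n_e, c, s = data.shape
    if s < 10 * order:
        raise ValueError(f"epoch length {s} < 10 * order {order}")
    t = s - order
    out = np.zeros((n_e, c, c))
    for e in range(n_e):
        x = data[e] - data[e].mean(axis=1, keepdims=True)
        lags = np.stack([
            np.stack([x[ch, order - l : s - l] for l in range(1, order + 1)])
            for ch in range(c)
        ])  # (C, p, T)
        y = x[:, order:]  # (C, T)
        flat = lags.reshape(c * order, t)
        gram = flat @ flat.T  # (C*p, C*p)
        xty = flat @ y.T  # (C*p, C)
        yty = np.einsum("ct,ct->c", y, y)
        rss_uni = np.empty(c)
        for j in range(c):
            sl = slice(j * order, (j + 1) * order)
            try:
                beta = np.linalg.solve(gram[sl, sl], xty[sl, j])
            except np.linalg.LinAlgError as err:
                raise np.linalg.LinAlgError(
                    f"singular univariate AR fit: epoch {e}, channel {j}"
                ) from err
            rss_uni[j] = yty[j] - xty[sl, j] @ beta
        for j in range(c):
            sj = slice(j * order, (j + 1) * order)
            for i in range(c):
                if i == j:
                    continue
                si = slice(i * order, (i + 1) * order)
                idx = np.r_[sj, si]
                m = gram[np.ix_(idx, idx)]
                rhs = xty[idx, j]
                try:
                    beta = np.linalg.solve(m, rhs)
                except np.linalg.LinAlgError as err:
                    raise np.linalg.LinAlgError(
                        f"singular bivariate AR fit: epoch {e}, pair ({i}, {j})"
                    ) from err
                rss_biv = yty[j] - rhs @ beta
                out[e, i, j] = max(math.log(rss_uni[j] / max(rss_biv, 1e-300)), 0.0)
    return out


def connectivity_matrices(
    ep: EpochedEEG,
    measure: str,
    band=None,
    gc_order: int = 5,
    exclude_edges: bool = False,
) -> ConnectivityTensor:
    """Full per-epoch connectivity matrices for one measure x band.

    GC is only defined on the broadband signal; requesting it with a narrow
    band raises.  Undirected measures return symmetric matrices with the
    measure's diagonal convention.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; known: {MEASURES}")
    if measure == "gc":
        band = get_band(band) if band is not None else BANDS["broadband"]
        if band.name != "broadband":
            raise ValueError("GC is computed on the broadband signal only")
        values = _gc_matrices(ep.data, gc_order)
        return ConnectivityTensor(values, "gc", band, directed=True, complex_valued=False,
                                  subject_id=ep.subject_id, session=ep.session, task=ep.task)
    band = get_band(band)
    if measure == "mi":
        epochs = analytic_band(ep, band)
        values = _mi_matrices(epochs, exclude_edges)
    else:
        stack = _analytic_stack(ep, band)
        if exclude_edges:
            k = int(round(0.1 * stack.shape[-1]))
            stack = stack[..., k : stack.shape[-1] - k]
        if measure == "plv":
            values = _plv_matrices(stack)
        elif measure == "wpli":
            values = _wpli_matrices(stack)
        else:
            m = _cpcc_matrices(stack)
            if measure == "cpcc":
                values = m
            elif measure == "abs_cpcc":
                values = np.abs(m)
                for e in range(values.shape[0]):
                    np.fill_diagonal(values[e], 1.0)
            else:  # i_cpcc
                values = m.imag
                for e in range(values.shape[0]):
                    np.fill_diagonal(values[e], 0.0)
    return ConnectivityTensor(
        values, measure, band, directed=False,
        complex_valued=(measure == "cpcc"),
        subject_id=ep.subject_id, session=ep.session, task=ep.task,
    )


# ---------------------------------------------------------------------------
# feature vectorization
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Epochs x vectorized pair features, with provenance per feature.

    ``pair_index`` maps feature column -> (i, j, component) where component
    is "" for plain values, "re"/"im" for the two CPCC components, and
    i -> j is the source -> target direction for GC.
    """

    matrix: np.ndarray  # (n_epochs, n_features) float
    pair_index: list[tuple[int, int, str]]
    labels: np.ndarray  # per-epoch session label ("before"/"after")
    subject_ids: np.ndarray
    measure: str
    band: str
    task: str
    convention: str

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels)
        self.subject_ids = np.asarray(self.subject_ids)
        if self.matrix.shape[1] != len(self.pair_index):
            raise ValueError("pair_index length must equal feature count")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]


def _half_pairs(c: int, convention: str, directed: bool) -> list[tuple[int, int, str]]:
    if directed:
        if convention == "paper_half":
            return [(i, j, "") for i in range(c) for j in range(c)]
        if convention == "full_offdiag":
            return [(i, j, "") for i in range(c) for j in range(c) if i != j]
        raise ValueError("directed measures support paper_half or full_offdiag only")
    pairs = [(i, j, "") for i in range(c) for j in range(i + 1, c)]
    if convention == "upper_triangle":
        return pairs
    if convention == "paper_half":
        if c % 2:
            raise ValueError("paper_half needs an even channel count")
        return pairs + [(i, i, "") for i in range(c // 2)]
    if convention == "full_offdiag":
        return [(i, j, "") for i in range(c) for j in range(c) if i != j]
    raise ValueError(f"unknown convention {convention!r}")


def vectorize_features(t: ConnectivityTensor, convention: str = "upper_triangle") -> FeatureTable:
    """Vectorize a connectivity tensor into an epochs x features table.

    ``upper_triangle`` gives the C(C-1)/2 unordered pairs; ``paper_half``
    adds the first C/2 diagonal cells for undirected measures (C^2/2 features
    total, e.g. 7442 at 122 channels) and uses the full ordered matrix for
    directed measures (C^2, e.g. 14884).  The complex CPCC contributes two
    features (re, im) per cell.
    """
    pairs = _half_pairs(t.n_channels, convention, t.directed)
    cols = []
    index: list[tuple[int, int, str]] = []
    for (i, j, _) in pairs:
        v = t.values[:, i, j]
        if t.complex_valued:
            cols.append(v.real)
            index.append((i, j, "re"))
            cols.append(v.imag)
            index.append((i, j, "im"))
        else:
            cols.append(np.real(v))
            index.append((i, j, ""))
    matrix = np.stack(cols, axis=1) if cols else np.empty((t.n_epochs, 0))
    n = t.n_epochs
    return FeatureTable(
        matrix=matrix,
        pair_index=index,
        labels=np.full(n, t.session if t.session else "?"),
        subject_ids=np.full(n, t.subject_id if t.subject_id else "?"),
        measure=t.measure,
        band=t.band.name,
        task=t.task,
        convention=convention,
    )


def concat_feature_tables(tables: list[FeatureTable]) -> FeatureTable:
    """Stack per-recording tables row-wise; all must share the feature space."""
    if not tables:
        raise ValueError("no tables to concatenate")
    first = tables[0]
    for t in tables[1:]:
        if t.pair_index != first.pair_index or t.measure != first.measure \
                or t.band != first.band or t.convention != first.convention:
            raise ValueError("feature spaces differ between tables")
    return FeatureTable(
        matrix=np.vstack([t.matrix for t in tables]),
        pair_index=list(first.pair_index),
        labels=np.concatenate([t.labels for t in tables]),
        subject_ids=np.concatenate([t.subject_ids for t in tables]),
        measure=first.measure,
        band=first.band,
        task=first.task,
        convention=first.convention,
    )
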