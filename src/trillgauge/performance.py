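"""Vocal performance metrics: deviation from the performance frontier and
trill consistency.

Trilled song trades frequency bandwidth against syllable repetition rate:
no male can maximise both, so the population's (rate, bandwidth) cloud is
triangular with a linear upper edge.  That edge — the performance limit —
is estimated by upper-bound regression: ordinary least squares through the
maximum-bandwidth trill in each trill-rate bin.  Vocal deviation is the
orthogonal distance of a trill from the limit (smaller = closer to the
frontier = harder trill); trill consistency is the mean pairwise
spectrogram cross-correlation among a trill's syllables (higher = more
precise repetition).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PerformanceLimit",
    "TrillPerformance",
    "upper_bound_regression",
    "vocal_deviation",
    "syllable_xcorr",
    "pairwise_xcorr_matrix",
    "trill_consistency",
    "consistency_transform",
]


@dataclass(frozen=True)
class PerformanceLimit:
    """Fitted upper-bound line ``bandwidth = slope * rate + intercept`` (Hz)."""

    slope: float
    intercept: float
    n_bins: int
    bin_width: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope) or not np.isfinite(self.intercept):
            raise ValueError("performance limit coefficients must be finite")

    def bandwidth_at(self, rate):
        return self.slope * np.asarray(rate, float) + self.intercept


@dataclass
class TrillPerformance:
    deviation: float
    consistency: float
    consistency_transformed: float


def upper_bound_regression(
    rates: np.ndarray,
    bandwidths: np.ndarray,
    bin_width: float = 2.0,
    min_bins: int = 5,
) -> PerformanceLimit:
    """Estimate the performance limit by regression through bin maxima.

    Trill rates are partitioned into fixed-width bins; within each occupied
    bin the trill with the maximum bandwidth is retained, and OLS through
    those maximum points gives the limit.

    Parameters
    ----------
    rates, bandwidths : per-trill rate (syll/s) and bandwidth (Hz)
    bin_width : trill-rate bin width in syll/s (default 2)
    min_bins : minimum occupied bins required (default 5)
    """
    T = np.asarray(rates, dtype=float)
    B = np.asarray(bandwidths, dtype=float)
    if T.shape != B.shape or T.ndim != 1:
        raise ValueError("rates and bandwidths must be matching 1-D arrays")
    ok = np.isfinite(T) & np.isfinite(B)
    T, B = T[ok], B[ok]
    if T.size == 0 or np.ptp(T) == 0:
        raise ValueError("trill rates have zero variance; cannot bin")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")

    bin_idx = np.floor(T / bin_width).astype(int)
    uniq = np.unique(bin_idx)
    if uniq.size < min_bins:
        raise ValueError(
            f"only {uniq.size} occupied trill-rate bins (need >= {min_bins}); "
            "use a smaller bin_width or more data"
        )
    max_T = np.empty(uniq.size)
    max_B = np.empty(uniq.size)
    for k, u in enumerate(uniq):
        sel = bin_idx == u
        j = np.argmax(B[sel])
        max_T[k] = T[sel][j]
        max_B[k] = B[sel][j]
    slope, intercept = np.polyfit(max_T, max_B, 1)
    return PerformanceLimit(
        slope=float(slope),
        intercept=float(intercept),
        n_bins=int(uniq.size),
        bin_width=float(bin_width),
    )


def vocal_deviation(rates, bandwidths, limit: PerformanceLimit):
    """Signed orthogonal distance from (rate, bandwidth) to the limit line.

    ``D = (a*T + b - B) / sqrt(1 + a^2)`` with bandwidth in Hz: positive for
    trills below the limit (lower D = closer to the frontier = higher
    performance); trills above the line get negative D and are retained.
    """
    T = np.asarray(rates, dtype=float)
    B = np.asarray(bandwidths, dtype=float)
    a, b = limit.slope, limit.intercept
    D = (a * T + b - B) / np.sqrt(1.0 + a * a)
    if np.ndim(rates) == 0 and np.ndim(bandwidths) == 0:
        return float(D)
    return D


def _bound_and_mask(
    mag: np.ndarray,
    freqs: np.ndarray,
    freq_bounds: tuple[float, float] | None,
    masking_fraction: float,
    guard_hz: float,
) -> np.ndarray:
    out = np.array(mag, dtype=float, copy=True)
    if freq_bounds is not None:
        lo, hi = freq_bounds
        keep = (freqs >= lo - guard_hz) & (freqs <= hi + guard_hz)
        out[~keep, :] = 0.0
    if masking_fraction > 0:
        peak = out.max()
        if peak > 0:
            out[out < masking_fraction * peak] = 0.0
    return out


def syllable_xcorr(
    spec_a: np.ndarray,
    spec_b: np.ndarray,
    freqs: np.ndarray,
    freq_bounds: tuple[float, float] | None = None,
    masking_fraction: float = 0.5,
    guard_hz: float = 200.0,
) -> float:
    """Peak normalized spectrogram cross-correlation between two syllables.

    Both magnitude spectrograms must share the same frequency grid.  Rows
    outside ``[freq_bounds[0] - guard_hz, freq_bounds[1] + guard_hz]`` are
    zeroed (background-noise bounding), cells below ``masking_fraction`` of
    each spectrogram's own peak are zeroed (broadband masking), each matrix
    is zero-padded to twice its frame count, and the correlator slides over
    time lags only — no frequency shifting, so pitch differences lower the
    score.  The score is ``max_lag <A, B_lag> / (||A|| ||B||)`` in [0, 1].
    """
    A = np.asarray(spec_a, dtype=float)
    Bm = np.asarray(spec_b, dtype=float)
    if A.ndim != 2 or Bm.ndim != 2 or A.shape[0] != Bm.shape[0]:
        raise ValueError("spectrograms must be 2-D with identical frequency grids")
    if A.shape[0] != np.asarray(freqs).size:
        raise ValueError("frequency axis length does not match spectrogram rows")

    A = _bound_and_mask(A, freqs, freq_bounds, masking_fraction, guard_hz)
    Bm = _bound_and_mask(Bm, freqs, freq_bounds, masking_fraction, guard_hz)
    na = np.linalg.norm(A)
    nb = np.linalg.norm(Bm)
    if na == 0 or nb == 0:
        warnings.warn("all-zero masked spectrogram; cross-correlation score 0")
        return 0.0

    # correlate over time lags only, summing cross-products across frequency;
    # zero-padding to nfft >= la + lb - 1 makes circular = linear, so the
    # peak over the full circular range covers positive and negative lags
    n_lags = A.shape[1] + Bm.shape[1] - 1
    nfft = int(2 ** np.ceil(np.log2(n_lags)))
    Fa = np.fft.rfft(A, nfft, axis=1)
    Fb = np.fft.rfft(Bm, nfft, axis=1)
    cc = np.fft.irfft((Fa * Fb.conj()).sum(axis=0), nfft)
    score = cc.max() / (na * nb)
    return float(min(max(score, 0.0), 1.0))


def pairwise_xcorr_matrix(
    specs: list[np.ndarray],
    freqs: np.ndarray,
    freq_bounds: tuple[float, float] | None = None,
    masking_fraction: float = 0.5,
    guard_hz: float = 200.0,
) -> np.ndarray:
    """All unordered pairwise cross-correlation scores among syllables.

    Vectorised equivalent of calling :func:`syllable_xcorr` on every pair:
    syllables are bounded/masked once, padded to a common FFT length, and all
    cross-spectra are formed in one einsum.  Returns the (n, n) symmetric
    score matrix with ones on the diagonal.
    """
    n = len(specs)
    if n < 2:
        raise ValueError("need at least 2 syllables")
    proc = [
        _bound_and_mask(np.asarray(s, float), freqs, freq_bounds, masking_fraction, guard_hz)
        for s in specs
    ]
    norms = np.array([np.linalg.norm(p) for p in proc])
    tmax = max(p.shape[1] for p in proc)
    n_lags = 2 * tmax - 1
    nfft = int(2 ** np.ceil(np.log2(max(n_lags, 2))))
    F = np.stack(
        [np.fft.rfft(np.pad(p, ((0, 0), (0, tmax - p.shape[1]))), nfft, axis=1) for p in proc]
    )  # (n, F, nfft/2+1)
    cross = np.einsum("afw,bfw->abw", F, F.conj())
    cc = np.fft.irfft(cross, nfft, axis=2)
    # lags both positive and negative: peak over the full circular range is
    # the peak over linear lags because both matrices were zero-padded
    peak = cc.max(axis=2)
    denom = np.outer(norms, norms)
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = np.where(denom > 0, peak / denom, 0.0)
    np.clip(scores, 0.0, 1.0, out=scores)
    np.fill_diagonal(scores, 1.0)
    return scores


def trill_consistency(
    syllable_spectrograms: list[np.ndarray],
    freqs: np.ndarray,
    freq_bounds: tuple[float, float] | None = None,
    masking_fraction: float = 0.5,
    guard_hz: float = 200.0,
) -> float:
    """Mean pairwise cross-correlation score among a trill's syllables."""
    n = len(syllable_spectrograms)
    if n < 2:
        raise ValueError("consistency requires at least 2 syllables")
    scores = pairwise_xcorr_matrix(
        syllable_spectrograms, freqs, freq_bounds, masking_fraction, guard_hz
    )
    iu = np.triu_indices(n, k=1)
    return float(scores[iu].mean())


def consistency_transform(consistency, eps: float = 1e-6):
    """Variance-stabilising transform ``-ln(1 - C)``, capped near C = 1.

    Consistency values of exactly 1 (identical syllables) are capped at
    ``1 - eps`` so the transform stays finite.
    """
    C = np.asarray(consistency, dtype=float)
    if np.any((C < 0) | (C > 1)):
        raise ValueError("consistency must lie in [0, 1]")
    out = -np.log(1.0 - np.minimum(C, 1.0 - eps))
    if np.ndim(consistency) == 0:
        return float(out)
    return out
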