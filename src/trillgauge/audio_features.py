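"""Per-trill acoustic measurements from waveforms and selection-table annotations.

Measurement conventions follow common selection-based practice: times are
seconds from recording start, annotations are half-open ``[begin, end)``
intervals, frequencies are Hz, and energy quantities are computed from the
power spectrum so they are invariant to uniform gain changes (recording
distance).

Two spectrogram presets are provided: a fine-frequency preset for bandwidth
measurement (DFT 4096, hop 111, ~11.7 Hz grid at 48 kHz) and a coarser one
for syllable cross-correlation (DFT 1024, 80% overlap).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal.windows import hann

__all__ = [
    "SpectrogramParams",
    "TrillMeasures",
    "MEASUREMENT_PRESET",
    "CORRELATION_PRESET",
    "spectrogram",
    "energy_bandwidth",
    "measure_trill",
    "measure_annotation_table",
]


@dataclass(frozen=True)
class SpectrogramParams:
    """Hann-window STFT settings.

    Parameters
    ----------
    dft_size : int
        DFT length in samples; the frequency grid spacing is
        ``sample_rate / dft_size``.
    hop : int
        Hop between consecutive frames, in samples (``0 < hop <= dft_size``).
    """

    dft_size: int = 4096
    hop: int = 111

    def __post_init__(self) -> None:
        if not (0 < self.hop <= self.dft_size):
            raise ValueError(
                f"hop must satisfy 0 < hop <= dft_size, got hop={self.hop}, "
                f"dft_size={self.dft_size}"
            )

    def freq_step(self, sample_rate: float) -> float:
        """Frequency grid spacing in Hz per bin."""
        return sample_rate / self.dft_size

    def time_step(self, sample_rate: float) -> float:
        """Time grid spacing in seconds per frame."""
        return self.hop / sample_rate


#: Bandwidth-measurement preset: 4096 DFT, 111-sample hop (~80.1% overlap
#: of the effective analysis window), 11.72 Hz grid at 48 kHz.
MEASUREMENT_PRESET = SpectrogramParams(dft_size=4096, hop=111)

#: Cross-correlation preset: 1024-point FFT, Hann window, 80% overlap.
CORRELATION_PRESET = SpectrogramParams(dft_size=1024, hop=205)


@dataclass
class TrillMeasures:
    """Acoustic summary of a single trill."""

    trill_id: str
    rate: float  # syllables / s
    bandwidth: float  # Hz, 99%-energy bandwidth of the whole-trill selection
    pitch: float  # Hz, mean per-syllable 99%-energy high frequency
    duration: float  # s, first syllable onset -> last syllable offset
    time_in_song: float  # s, song start -> trill start
    trill_type: object = None
    low_hz: float = np.nan  # min over syllables of 99%-energy low bound
    high_hz: float = np.nan  # max over syllables of 99%-energy high bound
    n_syllables: int = 0
    syllable_bandwidths: list = field(default_factory=list)


def spectrogram(
    waveform: np.ndarray,
    sample_rate: float,
    params: SpectrogramParams = MEASUREMENT_PRESET,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Magnitude spectrogram on the preset's time-frequency grid.

    Returns
    -------
    freqs : (F,) array of bin-center frequencies in Hz
    times : (T,) array of frame-center times in seconds
    mag : (F, T) nonnegative magnitude (not power) matrix
    """
    waveform = np.asarray(waveform, dtype=float)
    if waveform.ndim != 1:
        raise ValueError("waveform must be 1-D mono audio")
    if waveform.size < params.dft_size:
        # zero-pad short syllables up to one analysis window rather than fail;
        # genuinely empty input is an error
        if waveform.size == 0:
            raise ValueError("empty waveform")
        waveform = np.pad(waveform, (0, params.dft_size - waveform.size))
    win = hann(params.dft_size, sym=False)
    # frame k covers samples [k*hop, k*hop + dft_size); one batched FFT
    frames = sliding_window_view(waveform, params.dft_size)[:: params.hop]
    mag = np.abs(np.fft.rfft(frames * win, axis=1)).T
    freqs = np.arange(mag.shape[0]) * (sample_rate / params.dft_size)
    times = (np.arange(frames.shape[0]) * params.hop + params.dft_size / 2) / sample_rate
    return freqs, times, mag


def energy_bandwidth(
    power_spectrum: np.ndarray,
    freqs: np.ndarray,
    fraction: float = 0.99,
) -> tuple[float, float, float]:
    """Band containing `fraction` of spectral energy, trimming equal tails.

    The band is the smallest contiguous run of bins such that at most
    ``(1 - fraction) / 2`` of the total energy lies strictly below its lowest
    bin and strictly above its highest bin.  Returned bandwidth counts whole
    bins, so a single nonzero bin yields one grid-step of bandwidth.

    Parameters
    ----------
    power_spectrum : nonnegative (F,) array (power, not amplitude)
    freqs : (F,) bin-center frequencies, ascending and evenly spaced
    fraction : energy fraction to enclose, default 0.99

    Returns
    -------
    (low_hz, high_hz, bandwidth_hz)
    """
    p = np.asarray(power_spectrum, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if p.ndim != 1 or p.shape != freqs.shape:
        raise ValueError("power_spectrum and freqs must be matching 1-D arrays")
    if np.any(p < 0):
        raise ValueError("power spectrum must be nonnegative")
    total = p.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError("zero-energy spectrum: bandwidth undefined")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    tail = (1.0 - fraction) / 2.0 * total
    c = np.cumsum(p)
    # lowest bin that must be kept: energy strictly below it is <= tail
    low_idx = int(np.searchsorted(c, tail, side="left"))
    # energy strictly above bin j is total - c[j]
    above = total - c
    high_idx = int(np.searchsorted(-above, -tail, side="left"))
    high_idx = min(high_idx, p.size - 1)
    if high_idx < low_idx:  # degenerate: all energy in one bin
        high_idx = low_idx
    step = freqs[1] - freqs[0] if freqs.size > 1 else 0.0
    low_hz = freqs[low_idx]
    high_hz = freqs[high_idx]
    return low_hz, high_hz, high_hz - low_hz + step


def _segment(waveform: np.ndarray, sample_rate: float, begin_s: float, end_s: float) -> np.ndarray:
    i0 = int(round(begin_s * sample_rate))
    i1 = int(round(end_s * sample_rate))
    i0 = max(i0, 0)
    i1 = min(i1, waveform.size)
    if i1 <= i0:
        raise ValueError(f"empty selection [{begin_s}, {end_s})")
    return waveform[i0:i1]


def _power_spectrum(
    waveform: np.ndarray, sample_rate: float, params: SpectrogramParams
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled power spectrum of a selection (spectrogram power summed over frames)."""
    freqs, _, mag = spectrogram(waveform, sample_rate, params)
    return freqs, (mag**2).sum(axis=1)


def measure_trill(
    waveform: np.ndarray,
    sample_rate: float,
    syllables: pd.DataFrame,
    song_begin_s: float = 0.0,
    params: SpectrogramParams = MEASUREMENT_PRESET,
    fraction: float = 0.99,
    rate_mode: str = "count",
) -> TrillMeasures:
    """Measure one trill from its waveform and per-syllable annotation rows.

    Parameters
    ----------
    syllables : DataFrame with columns begin_s, end_s (and optionally
        trill_id, trill_type), one row per syllable, in temporal order.
    song_begin_s : start time of the containing song; ``time_in_song`` is the
        first syllable onset minus this.
    rate_mode : ``"count"`` (syllable count over onset->offset span, default)
        or ``"periods"`` (``(n-1)`` inter-onset periods over the
        first-onset -> last-onset span).
    """
    syl = syllables.sort_values("begin_s").reset_index(drop=True)
    n = len(syl)
    if n < 2:
        raise ValueError("a trill needs at least 2 annotated syllables")
    begins = syl["begin_s"].to_numpy(float)
    ends = syl["end_s"].to_numpy(float)
    if np.any(ends <= begins):
        raise ValueError("syllable annotations must have end_s > begin_s")
    if np.any(begins[1:] < ends[:-1] - 1e-9):
        raise ValueError("overlapping or out-of-order syllable annotations")

    span = ends[-1] - begins[0]
    if rate_mode == "count":
        rate = n / span
    elif rate_mode == "periods":
        rate = (n - 1) / (begins[-1] - begins[0])
    else:
        raise ValueError(f"unknown rate_mode {rate_mode!r}")

    # one spectrogram of the whole trill selection; the pooled power spectrum
    # gives the trill bandwidth, frame subsets give per-syllable bounds
    trill_wav = _segment(waveform, sample_rate, begins[0], ends[-1])
    freqs, times, mag = spectrogram(trill_wav, sample_rate, params)
    power = mag**2
    _, _, bandwidth = energy_bandwidth(power.sum(axis=1), freqs, fraction)

    # per-syllable bounds -> pitch (mean high frequency) and trill extrema;
    # a frame belongs to a syllable when its center falls inside it
    sylls_low, sylls_high, sylls_bw = [], [], []
    for b, e in zip(begins, ends):
        sel = (times >= b - begins[0]) & (times < e - begins[0])
        if not np.any(sel):
            sel = np.argmin(np.abs(times - (0.5 * (b + e) - begins[0])))
            ps = power[:, sel]
        else:
            ps = power[:, sel].sum(axis=1)
        lo, hi, bw = energy_bandwidth(ps, freqs, fraction)
        sylls_low.append(lo)
        sylls_high.append(hi)
        sylls_bw.append(bw)

    trill_id = str(syl["trill_id"].iloc[0]) if "trill_id" in syl else ""
    trill_type = syl["trill_type"].iloc[0] if "trill_type" in syl else None
    return TrillMeasures(
        trill_id=trill_id,
        rate=rate,
        bandwidth=bandwidth,
        pitch=float(np.mean(sylls_high)),
        duration=span,
        time_in_song=max(begins[0] - song_begin_s, 0.0),
        trill_type=trill_type,
        low_hz=float(np.min(sylls_low)),
        high_hz=float(np.max(sylls_high)),
        n_syllables=n,
        syllable_bandwidths=sylls_bw,
    )


def measure_annotation_table(
    waveform: np.ndarray,
    sample_rate: float,
    table: pd.DataFrame,
    params: SpectrogramParams = MEASUREMENT_PRESET,
    rate_mode: str = "count",
) -> pd.DataFrame:
    """Measure every trill in a selection table for one recording.

    The table holds one row per syllable with columns ``song_id, trill_id,
    syllable_idx, begin_s, end_s, low_hz, high_hz, trill_type``.  Song start
    is taken as the earliest annotated onset within each ``song_id``.
    """
    rows = []
    song_starts = table.groupby("song_id")["begin_s"].min()
    for (song_id, trill_id), syl in table.groupby(["song_id", "trill_id"], sort=True):
        m = measure_trill(
            waveform,
            sample_rate,
            syl,
            song_begin_s=float(song_starts.loc[song_id]),
            params=params,
            rate_mode=rate_mode,
        )
        rows.append(
            {
                "song_id": song_id,
                "trill_id": trill_id,
                "trill_type": m.trill_type,
                "rate": m.rate,
                "bandwidth": m.bandwidth,
                "pitch": m.pitch,
                "duration": m.duration,
                "time_in_song": m.time_in_song,
                "low_hz": m.low_hz,
                "high_hz": m.high_hz,
                "n_syllables": m.n_syllables,
            }
        )
    return pd.DataFrame(rows)
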