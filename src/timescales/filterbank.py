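"""Timescale separation: FIR band-pass filter bank over word index.

A language timescale is operationalised as the set of spectral components
of the word-rate stimulus embedding whose period (in words) falls in a
given range.  Eight octave-spaced period ranges are used: 2-4, 4-8, 8-16,
16-32, 32-64, 64-128, 128-256 and 256+ words.  Each band is extracted by
a zero-phase FIR filter built with the window method: a cosine at the
band's centre frequency multiplied by a Blackman window, normalised to
unit peak gain.  Convolving the p x w stimulus embedding with each filter
yields eight timescale-specific embeddings of the same shape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

#: Period (words) at which the open-ended top band ("256+") is closed,
#: continuing the octave spacing of the lower bands.
TOP_BAND_CLOSURE = 512.0


@dataclass(frozen=True)
class BandSpec:
    """One timescale band: a period range in words and its nominal timescale.

    The nominal timescale ``t`` is the arithmetic centre of the period
    range, ``(p_low + p_high) / 2``.
    """

    p_low: float
    p_high: float

    def __post_init__(self) -> None:
        if self.p_low < 2:
            raise ValueError(f"p_low must be >= 2 words, got {self.p_low}")
        if self.p_low >= self.p_high:
            raise ValueError(f"band requires p_low < p_high, got ({self.p_low}, {self.p_high})")

    @property
    def timescale(self) -> float:
        return 0.5 * (self.p_low + self.p_high)

    @property
    def geometric_timescale(self) -> float:
        return float(np.sqrt(self.p_low * self.p_high))

    @property
    def freq_range(self) -> tuple[float, float]:
        """Pass-band in cycles/word: (1/p_high, 1/p_low)."""
        return (1.0 / self.p_high, 1.0 / self.p_low)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.p_low:g}-{self.p_high:g} words"


def default_bands(top_closure: float = TOP_BAND_CLOSURE) -> list[BandSpec]:
    """The eight standard octave bands, the open top band closed at 512 words."""
    edges = [2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 128.0, 256.0, float(top_closure)]
    return [BandSpec(lo, hi) for lo, hi in zip(edges[:-1], edges[1:])]


def band_timescales(bands: list[BandSpec] | None = None) -> np.ndarray:
    """Nominal timescales t_i (words) of ``bands`` (default: the eight bands)."""
    if bands is None:
        bands = default_bands()
    return np.array([b.timescale for b in bands])


@dataclass(frozen=True)
class FilterBank:
    """Ordered band specs plus their FIR tap vectors (n_bands x n_taps).

    Taps are symmetric about the centre tap, so centred application is
    zero phase; each tap vector is scaled to unit peak magnitude response.
    """

    bands: tuple[BandSpec, ...]
    taps: np.ndarray

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    @property
    def n_taps(self) -> int:
        return self.taps.shape[1]

    @property
    def timescales(self) -> np.ndarray:
        return np.array([b.timescale for b in self.bands])


def design_filter_bank(
    bands: list[BandSpec] | None = None,
    n_taps: int = 2049,
    center: str = "arithmetic",
) -> FilterBank:
    """Window-method design of the timescale filter bank.

    Each band's taps are ``cos(2*pi*f_i*k) * blackman(n_taps)`` with ``k``
    centred at zero and ``f_i = 1/t_i`` cycles/word; ``t_i`` is the
    arithmetic band centre by default (``center="geometric"`` uses the
    geometric centre).  Taps are normalised to unit peak magnitude
    response, so pass-band gain is comparable across bands.

    ``n_taps`` must be odd (symmetric, zero-phase) and at least twice the
    longest period in the bank so the longest band is resolvable.
    """
    if bands is None:
        bands = default_bands()
    if not bands:
        raise ValueError("band list must be non-empty")
    if n_taps < 3 or n_taps % 2 == 0:
        raise ValueError(f"n_taps must be odd and >= 3, got {n_taps}")
    p_max = max(b.p_high for b in bands)
    if n_taps < 2 * p_max:
        worst = max(bands, key=lambda b: b.p_high)
        raise ValueError(
            f"n_taps={n_taps} too short for band {worst}: need >= {2 * p_max:g} taps"
        )
    if center not in ("arithmetic", "geometric"):
        raise ValueError("center must be 'arithmetic' or 'geometric'")

    k = np.arange(n_taps) - n_taps // 2
    window = np.blackman(n_taps)
    taps = np.empty((len(bands), n_taps))
    for i, band in enumerate(bands):
        t = band.timescale if center == "arithmetic" else band.geometric_timescale
        b = np.cos(2 * np.pi * k / t) * window
        peak = np.abs(np.fft.rfft(b, _fft_size(n_taps))).max()
        taps[i] = b / peak
    return FilterBank(bands=tuple(bands), taps=taps)


def _fft_size(n_taps: int) -> int:
    # enough resolution to locate the peak of slow filters accurately
    return max(1 << 18, 8 * n_taps)


def mirror_pad(matrix: np.ndarray, pad: int) -> np.ndarray:
    """Concatenate time-reversed copies of the edges along the last axis.

    ``[a, b, c]`` with ``pad=2`` becomes ``[b, a | a, b, c | c, b]``.  When
    ``pad`` exceeds the signal length the reflection is repeated
    (alternating direction) until the requested length is reached.
    """
    if pad < 0:
        raise ValueError("pad must be non-negative")
    if pad == 0:
        return matrix
    width = [(0, 0)] * (matrix.ndim - 1) + [(pad, pad)]
    return np.pad(matrix, width, mode="symmetric")


def apply_filter_bank(matrix: np.ndarray, bank: FilterBank) -> list[np.ndarray]:
    """Convolve each filter with the embedding, centred and mirror-padded.

    Parameters
    ----------
    matrix
        Stimulus embedding, shape ``(p, w)`` (or any ``(..., w)``).
    bank
        Filter bank from :func:`design_filter_bank`.

    Returns
    -------
    One ``(p, w)`` filtered embedding per band, in band order.  The
    symmetric taps plus centred alignment make filtering zero phase, and
    mirror padding avoids edge distortion.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[-1] < 1:
        raise ValueError("embedding must contain at least one word")
    pad = (bank.n_taps - 1) // 2
    padded = mirror_pad(matrix, pad)
    out = []
    for taps in bank.taps:
        full = fftconvolve(padded, taps[np.newaxis, :] if matrix.ndim == 2 else taps, axes=-1)
        # 'full' conv of (w + 2*pad) with (2*pad + 1) taps: centred output
        # starts at 2*pad and spans w samples.
        out.append(full[..., 2 * pad : 2 * pad + matrix.shape[-1]])
    return out


def frequency_response(bank: FilterBank, n_freq: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Magnitude response of each band; returns (freqs cycles/word, |H| per band)."""
    nfft = _fft_size(bank.n_taps) if n_freq is None else n_freq
    H = np.abs(np.fft.rfft(bank.taps, nfft, axis=-1))
    freqs = np.fft.rfftfreq(nfft)
    return freqs, H


def leakage_report(bank: FilterBank) -> pd.DataFrame:
    """Per-band QC table of in-band and far-out-of-band gain.

    For each band: the maximum gain inside its own period range, the
    maximum gain at frequencies inside bands two or more positions away,
    and the DC gain.  Well-sized taps give in-band gain >= 0.5 and DC
    gain < 0.01 for every band.
    """
    freqs, H = frequency_response(bank)
    rows = []
    for i, band in enumerate(bank.bands):
        lo, hi = band.freq_range
        in_band = H[i, (freqs >= lo) & (freqs <= hi)].max()
        far = 0.0
        for j, other in enumerate(bank.bands):
            if abs(j - i) < 2:
                continue
            olo, ohi = other.freq_range
            sel = (freqs >= olo) & (freqs <= ohi)
            if sel.any():
                far = max(far, H[i, sel].max())
        rows.append(
            {
                "band": str(band),
                "timescale": band.timescale,
                "in_band_gain": in_band,
                "far_band_gain": far,
                "dc_gain": H[i, 0],
            }
        )
    return pd.DataFrame(rows)
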