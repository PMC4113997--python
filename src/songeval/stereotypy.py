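"""Syllable stereotypy and bout-level song maturity from spectrogram correlations.

Syllable stereotypy asks how reproducible a bird's syllables are,
independent of their order: pairs of syllable spectrograms are compared by
the peak of their lag-correlation function, and the 95th percentile of
each selected syllable's similarity distribution is averaged over selected
syllables.  The maturity index applies the same spectrogram
cross-correlation peak to whole song bouts, a quantity that rises steadily
over song development.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .audio_features import (ANALYSIS_BAND_HZ, AudioClip, SpectrogramMT,
                             SpectrogramParams, compute_multitaper_spectrogram)


@dataclass
class SyllableDatabase:
    """A bird's syllable collection as precomputed multitaper spectrograms."""

    spectrograms: list[SpectrogramMT]
    labels: list[str] | None = None

    @classmethod
    def from_clips(cls, clips: list[AudioClip],
                   params: SpectrogramParams | None = None,
                   labels: list[str] | None = None) -> "SyllableDatabase":
        return cls([compute_multitaper_spectrogram(c, params) for c in clips], labels)

    def __len__(self) -> int:
        return len(self.spectrograms)


@dataclass
class StereotypyResult:
    per_selected_p95: np.ndarray
    stereotypy: float
    n_selected: int
    n_sampled_per_selected: int


def _band_zscore(spec: SpectrogramMT, band_hz: tuple[float, float]
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Z-score each 1 ms power slice over the band bins.

    Returns (Z, valid): Z is (n_freq, n_time) with silent slices zeroed
    out, valid flags the usable slices.  A slice is silent if its variance
    is zero or its total band power falls below the amplitude gate
    (noise floor + 12 dB, capped 20 dB below the loudest slice) — the same
    silence convention used in feature extraction, so background noise in
    the gaps does not dilute the diagonal means.
    """
    from .audio_features import SILENCE_FLOOR_DB, _default_threshold
    idx = spec.band_indices(band_hz)
    if idx.size < 2:
        raise ValueError("analysis band contains fewer than 2 frequency bins")
    p = spec.power[:, idx].T.astype(float)          # (n_freq, n_time)
    total = p.sum(axis=0)
    with np.errstate(divide="ignore"):
        amp_db = np.maximum(10.0 * np.log10(np.maximum(total, np.finfo(float).tiny)),
                            SILENCE_FLOOR_DB)
    mu = p.mean(axis=0)
    sd = p.std(axis=0)
    valid = (sd > 0) & (amp_db >= _default_threshold(amp_db))
    z = np.zeros_like(p)
    z[:, valid] = (p[:, valid] - mu[valid]) / sd[valid]
    return z, valid


def spectrogram_similarity(a: SpectrogramMT, b: SpectrogramMT,
                           band_hz: tuple[float, float] = ANALYSIS_BAND_HZ,
                           min_overlap_frac: float = 0.5,
                           return_lag: bool = False):
    """Peak of the lag-correlation function between two spectrograms.

    The correlation matrix holds the Pearson correlation of band-restricted
    (860 Hz - 8.6 kHz by default) power spectra between each pair of 1 ms
    slices; summing along diagonals, normalized by the number of
    overlapping valid slices, gives the lag-correlation function, whose
    maximum (over lags with at least ``min_overlap_frac`` of the shorter
    spectrogram overlapping) is returned.  Lag is the shift of ``b``
    relative to ``a`` in frames: if ``b`` repeats ``a`` delayed by 15
    frames the peak sits at lag +15.

    Zero-variance (silent) slices are excluded from the diagonal
    normalization.
    """
    if a.power.shape[1] != b.power.shape[1] or not np.allclose(a.freqs, b.freqs):
        raise ValueError("spectrograms must share one frequency grid")
    za, va = _band_zscore(a, band_hz)
    zb, vb = _band_zscore(b, band_hz)
    n_freq = za.shape[0]
    na, nb = za.shape[1], zb.shape[1]
    # L(delta) = sum_i r(a_i, b_{i+delta}) realized as per-channel cross-correlation
    num = fftconvolve(zb, za[:, ::-1], mode="full", axes=1).sum(axis=0)
    cnt = np.convolve(vb.astype(float), va[::-1].astype(float), mode="full")
    lags = np.arange(-(na - 1), nb)
    # overlap is counted over valid (sounding) slices only
    min_overlap = max(1, int(np.ceil(min_overlap_frac * min(va.sum(), vb.sum()))))
    ok = cnt >= min_overlap - 0.5
    if not ok.any():
        raise ValueError("no lag satisfies the minimum-overlap requirement")
    with np.errstate(invalid="ignore"):
        lagcorr = np.where(ok, num / (n_freq * np.maximum(cnt, 1)), -np.inf)
    k = int(np.argmax(lagcorr))
    peak = float(min(lagcorr[k], 1.0))
    if return_lag:
        return peak, int(lags[k])
    return peak


def syllable_stereotypy(db: SyllableDatabase, n_select: int = 100,
                        n_sample: int = 100,
                        seed: int | np.random.Generator | None = None,
                        exclude_self: bool = True,
                        sample_with_replacement: bool = True,
                        percentile: float = 95.0,
                        band_hz: tuple[float, float] = ANALYSIS_BAND_HZ
                        ) -> StereotypyResult:
    """Syllable stereotypy of a database.

    ``n_select`` syllables are drawn without replacement; for each, a sample
    of ``n_sample`` syllables is drawn (with replacement by default,
    excluding the selected syllable itself) and the distribution of
    pairwise spectrogram similarities is summarized by its ``percentile``
    (95th, linear interpolation between closest ranks).  Stereotypy is the
    mean of those per-selected values.
    """
    if len(db) < n_select:
        raise ValueError(f"database of {len(db)} syllables < n_select={n_select}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    selected = rng.choice(len(db), size=n_select, replace=False)
    p95 = np.empty(n_select)
    for k, i in enumerate(selected):
        pool = np.delete(np.arange(len(db)), i) if exclude_self else np.arange(len(db))
        sample = rng.choice(pool, size=n_sample, replace=sample_with_replacement)
        sims = [spectrogram_similarity(db.spectrograms[i], db.spectrograms[j],
                                       band_hz=band_hz) for j in sample]
        p95[k] = np.percentile(sims, percentile)
    return StereotypyResult(per_selected_p95=p95, stereotypy=float(p95.mean()),
                            n_selected=n_select, n_sampled_per_selected=n_sample)


def maturity_index(bouts: list[AudioClip | SpectrogramMT],
                   params: SpectrogramParams | None = None,
                   band_hz: tuple[float, float] = ANALYSIS_BAND_HZ) -> float:
    """Mean peak spectrogram cross-correlation over all bout pairs.

    Measures bout-to-bout song stereotypy; mature crystallized song scores
    near 1, variable juvenile song lower.
    """
    if len(bouts) < 2:
        raise ValueError("maturity_index requires at least 2 bouts")
    specs = [b if isinstance(b, SpectrogramMT) else compute_multitaper_spectrogram(b, params)
             for b in bouts]
    vals = [spectrogram_similarity(specs[i], specs[j], band_hz=band_hz)
            for i in range(len(specs)) for j in range(i + 1, len(specs))]
    return float(np.mean(vals))
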