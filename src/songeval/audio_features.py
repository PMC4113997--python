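"""Multitaper spectrograms, SAP-style acoustic features and syllable segmentation.

All song-analysis stages run on a common time-frequency representation: a
multitaper spectrogram with a 10 ms analysis window advanced in 1 ms steps
(k = 2 DPSS tapers, time-bandwidth 1.5), from which per-frame acoustic
features in the Sound-Analysis-Pro tradition are derived — amplitude,
frequency modulation, Wiener entropy, pitch goodness and pitch.  Feature
analysis is restricted to the 860 Hz – 8.6 kHz band throughout.

Conventions: times are in milliseconds from clip start, frame timestamps are
window centers, intervals are half-open ``[onset, offset)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal.windows import dpss

#: Analysis band (Hz) shared by feature extraction and stereotypy scoring.
ANALYSIS_BAND_HZ = (860.0, 8600.0)

#: Default amplitude floor (dB) assigned to silence-flagged frames.
SILENCE_FLOOR_DB = -100.0


@dataclass(frozen=True)
class SpectrogramParams:
    """Multitaper spectrogram parameters (defaults match the analysis pipeline)."""

    n_tapers: int = 2
    bandwidth_param: float = 1.5  # DPSS time-bandwidth product NW
    window_ms: float = 10.0
    step_ms: float = 1.0


@dataclass
class AudioClip:
    """A mono audio clip: raw samples plus sample rate in Hz."""

    samples: np.ndarray
    sample_rate: float = 40_000.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("AudioClip requires mono (1-D) samples; got "
                             f"{self.samples.ndim}-D input")
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")

    @property
    def duration_ms(self) -> float:
        return 1000.0 * len(self.samples) / self.sample_rate


@dataclass
class SpectrogramMT:
    """Multitaper spectrogram: linear power, frame times (ms) and freqs (Hz)."""

    power: np.ndarray          # (n_frames, n_freqs), linear power, >= 0
    frame_times: np.ndarray    # ms, window centers
    freqs: np.ndarray          # Hz
    params: SpectrogramParams

    @property
    def n_frames(self) -> int:
        return self.power.shape[0]

    def band_indices(self, band_hz: tuple[float, float] = ANALYSIS_BAND_HZ) -> np.ndarray:
        lo, hi = band_hz
        return np.flatnonzero((self.freqs >= lo) & (self.freqs <= hi))


@dataclass
class FeatureTrack:
    """Per-frame acoustic features at the spectrogram frame rate.

    ``silent`` flags frames whose band power fell below the silence
    threshold; flagged frames carry the silence convention values
    (amplitude = floor dB, wiener_entropy = 0, pitch_goodness = 0,
    pitch = 0 Hz) and are excluded from feature histograms and from
    similarity-diagonal means downstream.
    """

    frame_times: np.ndarray     # ms
    amplitude: np.ndarray       # dB
    fm: np.ndarray              # degrees, [0, 90]
    wiener_entropy: np.ndarray  # log(geometric/arithmetic spectral mean), <= 0
    pitch_goodness: np.ndarray  # cepstral peak height, >= 0
    pitch: np.ndarray           # Hz
    silent: np.ndarray = field(default=None)  # bool mask

    def __post_init__(self) -> None:
        n = len(self.frame_times)
        for name in ("amplitude", "fm", "wiener_entropy", "pitch_goodness", "pitch"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"feature '{name}' length mismatch with frame_times")
        if self.silent is None:
            self.silent = np.zeros(n, dtype=bool)

    def __len__(self) -> int:
        return len(self.frame_times)

    @property
    def step_ms(self) -> float:
        if len(self.frame_times) < 2:
            return 1.0
        return float(self.frame_times[1] - self.frame_times[0])

    def feature_matrix(self, names: tuple[str, ...] = ("fm", "wiener_entropy",
                                                       "pitch_goodness", "pitch")) -> np.ndarray:
        """Stack the named features into an (n_frames, n_features) matrix."""
        return np.column_stack([np.asarray(getattr(self, n), dtype=float) for n in names])


@dataclass(frozen=True)
class SyllableSeg:
    """A syllable interval ``[onset_ms, offset_ms)`` within one song."""

    onset_ms: float
    offset_ms: float

    def __post_init__(self) -> None:
        if self.offset_ms <= self.onset_ms:
            raise ValueError(f"offset ({self.offset_ms}) must exceed onset ({self.onset_ms})")

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


def _default_threshold(amplitude: np.ndarray) -> float:
    """Amplitude gate: noise floor (10th percentile) + 12 dB, capped 20 dB
    below the loudest frame so all-sound clips keep their frames."""
    floor = max(float(np.percentile(amplitude, 10.0)), SILENCE_FLOOR_DB)
    return min(floor + 12.0, float(amplitude.max()) - 20.0)


def _frame_signal(x: np.ndarray, win: int, step: int) -> np.ndarray:
    """Return (n_frames, win) view of x with hop `step` (frame-count formula)."""
    n_frames = (len(x) - win) // step + 1
    view = np.lib.stride_tricks.sliding_window_view(x, win)
    return view[::step][:n_frames]


def compute_multitaper_spectrogram(clip: AudioClip,
                                   params: SpectrogramParams | None = None) -> SpectrogramMT:
    """Compute a multitaper spectrogram of a clip.

    Each 10 ms frame is multiplied by the first ``n_tapers`` DPSS tapers
    (time-bandwidth ``bandwidth_param``); the power is the average over the
    taper eigenspectra.  Frame count is
    ``floor((n_samples - window_samples)/step_samples) + 1``.
    """
    params = params or SpectrogramParams()
    sr = clip.sample_rate
    win = int(round(params.window_ms * sr / 1000.0))
    step = max(1, int(round(params.step_ms * sr / 1000.0)))
    if len(clip.samples) < win:
        raise ValueError(
            f"clip of {len(clip.samples)} samples shorter than one "
            f"{params.window_ms} ms window ({win} samples)")
    tapers = dpss(win, params.bandwidth_param, Kmax=params.n_tapers)  # (k, win)
    frames = _frame_signal(clip.samples, win, step)                   # (n_frames, win)
    # average over taper eigenspectra; (k, n_frames, n_freqs) is small enough
    spectra = np.fft.rfft(frames[None, :, :] * tapers[:, None, :], axis=-1)
    power = np.mean(np.abs(spectra) ** 2, axis=0)
    freqs = np.fft.rfftfreq(win, d=1.0 / sr)
    starts = np.arange(frames.shape[0]) * step
    frame_times = (starts + win / 2.0) * 1000.0 / sr
    return SpectrogramMT(power=power, frame_times=frame_times, freqs=freqs, params=params)


def _cepstral_pitch(log_power: np.ndarray, sr: float, win: int,
                    fmin_hz: float = 400.0, fmax_hz: float = 6000.0
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Pitch and pitch goodness from the real cepstrum of each frame.

    The cepstrum is the inverse FFT of the log power spectrum; a harmonic
    stack with fundamental f0 produces a peak at quefrency 1/f0.  Pitch
    goodness is the height of that peak, pitch the corresponding frequency.
    """
    cep = np.fft.irfft(log_power, n=win, axis=-1)
    quef = np.arange(win) / sr                      # seconds
    lo = max(2, int(np.ceil(sr / fmax_hz)))
    hi = min(win // 2, int(np.floor(sr / fmin_hz)))
    band = cep[:, lo:hi + 1]
    idx = np.argmax(band, axis=-1) + lo
    goodness = np.maximum(cep[np.arange(len(cep)), idx], 0.0)
    pitch = 1.0 / quef[idx]
    return pitch, goodness


def extract_features(clip: AudioClip,
                     params: SpectrogramParams | None = None,
                     band_hz: tuple[float, float] = ANALYSIS_BAND_HZ,
                     silence_threshold_db: float | None = None,
                     pitch_range_hz: tuple[float, float] = (400.0, 6000.0)
                     ) -> FeatureTrack:
    """Extract per-frame acoustic features from a clip.

    amplitude
        10*log10 of total band power.
    wiener_entropy
        log(geometric mean / arithmetic mean) of band power; 0 for white
        noise, strongly negative for pure tones (always <= 0 by Jensen).
    pitch, pitch_goodness
        location (Hz) and height of the cepstral peak in ``pitch_range_hz``.
    fm
        atan2 of time-derivative vs frequency-derivative spectral energy,
        in degrees: 0 for a steady tone, approaching 90 for fast sweeps.

    Frames whose amplitude falls below ``silence_threshold_db`` (default:
    noise floor + 12 dB, where the noise floor is the 10th percentile of
    frame amplitudes, capped 20 dB below the loudest frame so clips with
    no silent stretches are not gated away) are silence-flagged and carry
    the silence convention values.
    """
    spec = compute_multitaper_spectrogram(clip, params)
    idx = spec.band_indices(band_hz)
    if idx.size < 2:
        raise ValueError("analysis band contains fewer than 2 frequency bins")
    band_power = spec.power[:, idx]
    total = band_power.sum(axis=1)

    tiny = np.finfo(float).tiny
    with np.errstate(divide="ignore"):
        amplitude = 10.0 * np.log10(np.maximum(total, tiny))
    amplitude = np.maximum(amplitude, SILENCE_FLOOR_DB)

    if silence_threshold_db is None:
        silence_threshold_db = _default_threshold(amplitude)
    silent = amplitude < silence_threshold_db

    # Wiener entropy on band power
    logp = np.log(np.maximum(band_power, tiny))
    wiener = logp.mean(axis=1) - np.log(np.maximum(band_power.mean(axis=1), tiny))
    wiener = np.minimum(wiener, 0.0)

    # cepstral pitch on the full spectrum (harmonics above the band edge help)
    sr = clip.sample_rate
    win = int(round(spec.params.window_ms * sr / 1000.0))
    full_logp = np.log(np.maximum(spec.power, tiny))
    pitch, goodness = _cepstral_pitch(full_logp, sr, win, *pitch_range_hz)

    # FM from directional derivatives of band log-power
    dlog = np.log(np.maximum(band_power, tiny))
    dt = np.gradient(dlog, axis=0) if len(dlog) > 1 else np.zeros_like(dlog)
    df = np.gradient(dlog, axis=1)
    fm = np.degrees(np.arctan2(np.sqrt((dt ** 2).mean(axis=1)),
                               np.sqrt((df ** 2).mean(axis=1)) + tiny))

    # silence convention
    amplitude = np.where(silent, SILENCE_FLOOR_DB, amplitude)
    wiener = np.where(silent, 0.0, wiener)
    goodness = np.where(silent, 0.0, goodness)
    pitch = np.where(silent, 0.0, pitch)
    fm = np.where(silent, 0.0, fm)

    return FeatureTrack(frame_times=spec.frame_times, amplitude=amplitude, fm=fm,
                        wiener_entropy=wiener, pitch_goodness=goodness,
                        pitch=pitch, silent=silent)


def segment_syllables(track: FeatureTrack,
                      threshold_db: float | None = None,
                      min_syllable_ms: float = 10.0,
                      min_gap_ms: float = 5.0) -> list[SyllableSeg]:
    """Segment a song into syllables by amplitude gating.

    Maximal runs of frames with amplitude >= threshold become candidate
    syllables; gaps shorter than ``min_gap_ms`` are merged and runs shorter
    than ``min_syllable_ms`` discarded.  The default threshold is the
    clip's noise floor (10th percentile of frame amplitude) + 12 dB.
    """
    if len(track) == 0:
        return []
    amp = np.asarray(track.amplitude, dtype=float)
    if threshold_db is None:
        threshold_db = _default_threshold(amp)
    above = amp >= threshold_db
    if not above.any():
        return []
    step = track.step_ms
    t0 = float(track.frame_times[0])

    # maximal runs of True
    padded = np.concatenate([[False], above, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    runs = list(zip(edges[::2], edges[1::2]))  # [start, stop) frame indices

    # merge runs separated by gaps < min_gap_ms
    merged: list[list[int]] = []
    for start, stop in runs:
        if merged and (start - merged[-1][1]) * step < min_gap_ms:
            merged[-1][1] = stop
        else:
            merged.append([start, stop])

    segs = []
    for start, stop in merged:
        if (stop - start) * step >= min_syllable_ms:
            segs.append(SyllableSeg(onset_ms=t0 + start * step, offset_ms=t0 + stop * step))
    return segs


def feature_distribution_correlation(track_a: FeatureTrack, track_b: FeatureTrack,
                                     feature_name: str, n_bins: int = 50) -> float:
    """Pearson correlation between two feature histograms on a shared bin grid.

    Silence-flagged frames are excluded; histograms are normalized to unit
    area before correlating.  Used to quantify how much a bird's feature
    distributions (FM, Wiener entropy, pitch goodness, pitch) change between
    two recording epochs.
    """
    a = np.asarray(getattr(track_a, feature_name), dtype=float)[~track_a.silent]
    b = np.asarray(getattr(track_b, feature_name), dtype=float)[~track_b.silent]
    if a.size == 0 or b.size == 0:
        raise ValueError("feature_distribution_correlation needs non-empty tracks")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if hi <= lo:
        raise ValueError("degenerate single-bin histograms: correlation undefined")
    edges = np.linspace(lo, hi, n_bins + 1)
    ha, _ = np.histogram(a, bins=edges, density=True)
    hb, _ = np.histogram(b, bins=edges, density=True)
    if ha.std() == 0 or hb.std() == 0:
        raise ValueError("zero-variance histogram: correlation undefined")
    return float(np.corrcoef(ha, hb)[0, 1])
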