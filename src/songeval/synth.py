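"""Synthetic songs, spike trains and evoked traces with known ground truth.

Real zebra finch recordings cannot be redistributed with the package, so
every analysis stage is exercised on synthetic data whose ground truth is
known by construction:

* songs are built from harmonic-stack syllables (fundamental, harmonics,
  optional linear FM sweep) separated by silent gaps, repeated as motif
  renditions within a bout; a distortion specification degrades a pupil
  rendition relative to its tutor with pitch jitter, duration jitter,
  syllable drops, sequence shuffles and additive noise — all zero gives a
  sample-identical copy;
* spike trains are inhomogeneous Poisson: a constant baseline plus a
  rectangular rate increment of known latency, amplitude and duration
  after each event (rectangular so latency/duration ground truth is
  unambiguous);
* antidromic trials are Gaussian noise traces with an optional damped
  sinusoid injected after the stimulus.

All generators are deterministic under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .audio_features import AudioClip, SyllableSeg
from .neural import AntidromicTrialSet, EventTimes, SpikeTrain


@dataclass(frozen=True)
class SyllableSpec:
    """One harmonic-stack syllable."""

    f0_hz: float = 700.0
    n_harmonics: int = 5
    duration_ms: float = 80.0
    fm_sweep_hz_per_ms: float = 0.0
    amplitude_db: float = 0.0     # relative to full scale


@dataclass
class SongTemplate:
    """A motif: ordered syllables with silent gaps between them."""

    syllables: list[SyllableSpec]
    gaps_ms: list[float] | None = None      # gap after each syllable but the last
    motif_order: list[int] | None = None    # indices into `syllables`

    def __post_init__(self) -> None:
        if not self.syllables:
            raise ValueError("SongTemplate requires at least one syllable")
        n = len(self.motif_order) if self.motif_order else len(self.syllables)
        if self.gaps_ms is None:
            self.gaps_ms = [40.0] * (n - 1)
        if self.motif_order is None:
            self.motif_order = list(range(len(self.syllables)))

    @property
    def motif_duration_ms(self) -> float:
        dur = sum(self.syllables[i].duration_ms for i in self.motif_order)
        return dur + sum(self.gaps_ms)


def default_template() -> SongTemplate:
    """A three-syllable motif loosely shaped like a zebra finch motif."""
    return SongTemplate(syllables=[
        SyllableSpec(f0_hz=650.0, n_harmonics=6, duration_ms=90.0,
                     fm_sweep_hz_per_ms=0.0),
        SyllableSpec(f0_hz=950.0, n_harmonics=5, duration_ms=70.0,
                     fm_sweep_hz_per_ms=-2.0),
        SyllableSpec(f0_hz=1300.0, n_harmonics=4, duration_ms=60.0,
                     fm_sweep_hz_per_ms=3.0),
    ], gaps_ms=[40.0, 40.0])


@dataclass(frozen=True)
class DistortionSpec:
    """Controlled tutor-to-pupil degradation; all-zero means an exact copy."""

    pitch_jitter_sd: float = 0.0        # fractional SD on each syllable's f0
    duration_jitter_sd: float = 0.0     # fractional SD on syllable durations
    syllable_drop_prob: float = 0.0
    sequence_shuffle_prob: float = 0.0  # per-rendition probability of shuffling
    additive_noise_db: float | None = None  # dB re: unit peak; None = no noise

    def __post_init__(self) -> None:
        for name in ("syllable_drop_prob", "sequence_shuffle_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    @classmethod
    def from_level(cls, level: float) -> "DistortionSpec":
        """Map a scalar distortion level in [0, 1] onto all knobs at once.

        Level 0 is an exact copy; level 1 combines 8% pitch jitter, 10%
        duration jitter, 20% syllable drops, 30% sequence shuffles and
        -20 dB additive noise.
        """
        if level == 0:
            return cls()
        return cls(pitch_jitter_sd=0.08 * level,
                   duration_jitter_sd=0.10 * level,
                   syllable_drop_prob=0.20 * level,
                   sequence_shuffle_prob=0.30 * level,
                   additive_noise_db=-50.0 + 30.0 * level)

    @property
    def is_null(self) -> bool:
        return (self.pitch_jitter_sd == 0 and self.duration_jitter_sd == 0
                and self.syllable_drop_prob == 0 and self.sequence_shuffle_prob == 0
                and self.additive_noise_db is None)


def _render_syllable(spec: SyllableSpec, sample_rate: float) -> np.ndarray:
    n = int(round(spec.duration_ms * sample_rate / 1000.0))
    t = np.arange(n) / sample_rate                      # seconds
    f_inst = spec.f0_hz + spec.fm_sweep_hz_per_ms * 1000.0 * t
    phase0 = 2.0 * np.pi * np.cumsum(f_inst) / sample_rate
    x = np.zeros(n)
    for h in range(1, spec.n_harmonics + 1):
        x += np.sin(h * phase0) / h
    # 2 ms cosine on/off ramps to avoid clicks
    ramp = min(int(0.002 * sample_rate), n // 2)
    if ramp > 0:
        env = np.ones(n)
        r = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
        env[:ramp] = r
        env[-ramp:] = r[::-1]
        x *= env
    peak = np.max(np.abs(x))
    if peak > 0:
        x = x / peak * 10.0 ** (spec.amplitude_db / 20.0)
    return x


def generate_song(template: SongTemplate,
                  distortion: DistortionSpec = DistortionSpec(),
                  n_bouts: int = 1,
                  n_renditions: int = 3,
                  sample_rate: float = 40_000.0,
                  inter_motif_gap_ms: float = 120.0,
                  edge_pad_ms: float = 60.0,
                  seed: int | np.random.Generator | None = None
                  ) -> tuple[list[AudioClip], list[list[SyllableSeg]]]:
    """Render song bouts plus ground-truth syllable segmentation.

    Each bout holds ``n_renditions`` motif renditions separated by
    ``inter_motif_gap_ms``, padded with ``edge_pad_ms`` of silence at both
    ends (a placeholder for introductory notes).  Distortion is applied
    independently per rendition; with a null distortion the output is a
    deterministic, exact rendering of the template.

    Returns ``(bouts, ground_truth)`` with one list of
    :class:`~songeval.audio_features.SyllableSeg` per bout.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bouts, truths = [], []
    for _ in range(n_bouts):
        pieces = [np.zeros(int(edge_pad_ms * sample_rate / 1000.0))]
        segs: list[SyllableSeg] = []
        cursor_ms = edge_pad_ms
        for r in range(n_renditions):
            order = list(template.motif_order)
            if distortion.sequence_shuffle_prob > 0 and \
                    rng.random() < distortion.sequence_shuffle_prob:
                order = list(rng.permutation(order))
            for k, idx in enumerate(order):
                spec = template.syllables[idx]
                if distortion.pitch_jitter_sd > 0:
                    spec = replace(spec, f0_hz=spec.f0_hz *
                                   (1 + rng.normal(0, distortion.pitch_jitter_sd)))
                if distortion.duration_jitter_sd > 0:
                    spec = replace(spec, duration_ms=max(
                        5.0, spec.duration_ms *
                        (1 + rng.normal(0, distortion.duration_jitter_sd))))
                dropped = (distortion.syllable_drop_prob > 0 and
                           rng.random() < distortion.syllable_drop_prob)
                if dropped:
                    wav = np.zeros(int(round(spec.duration_ms * sample_rate / 1000.0)))
                else:
                    wav = _render_syllable(spec, sample_rate)
                dur_ms = 1000.0 * len(wav) / sample_rate
                if not dropped:
                    segs.append(SyllableSeg(cursor_ms, cursor_ms + dur_ms))
                pieces.append(wav)
                cursor_ms += dur_ms
                if k < len(order) - 1:
                    gap = template.gaps_ms[min(k, len(template.gaps_ms) - 1)]
                    pieces.append(np.zeros(int(round(gap * sample_rate / 1000.0))))
                    cursor_ms += 1000.0 * len(pieces[-1]) / sample_rate
            if r < n_renditions - 1:
                pieces.append(np.zeros(int(inter_motif_gap_ms * sample_rate / 1000.0)))
                cursor_ms += 1000.0 * len(pieces[-1]) / sample_rate
        pieces.append(np.zeros(int(edge_pad_ms * sample_rate / 1000.0)))
        x = np.concatenate(pieces)
        if distortion.additive_noise_db is not None:
            x = x + rng.normal(0.0, 10.0 ** (distortion.additive_noise_db / 20.0),
                               size=x.size)
        bouts.append(AudioClip(samples=x, sample_rate=sample_rate))
        truths.append(segs)
    return bouts, truths


def generate_tutor_motif_clip(template: SongTemplate,
                              sample_rate: float = 40_000.0,
                              edge_pad_ms: float = 20.0
                              ) -> tuple[AudioClip, list[SyllableSeg]]:
    """Render a single clean motif rendition (the tutor exemplar)."""
    bouts, truths = generate_song(template, DistortionSpec(), n_bouts=1,
                                  n_renditions=1, sample_rate=sample_rate,
                                  edge_pad_ms=edge_pad_ms, seed=0)
    return bouts[0], truths[0]


@dataclass(frozen=True)
class ResponseSpec:
    """A rectangular event-locked rate transient on a Poisson baseline."""

    baseline_rate_hz: float = 5.0
    latency_ms: float = 24.0
    amplitude_hz: float = 60.0
    duration_ms: float = 90.0
    jitter_sd_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.baseline_rate_hz < 0 or self.baseline_rate_hz + self.amplitude_hz < 0:
            raise ValueError("instantaneous rate must be non-negative everywhere")


def generate_spike_train(events: EventTimes, spec: ResponseSpec,
                         span_ms: float,
                         seed: int | np.random.Generator | None = None
                         ) -> SpikeTrain:
    """Inhomogeneous-Poisson spike train over ``[0, span_ms]``.

    Baseline spikes are homogeneous Poisson at ``baseline_rate_hz``; each
    event adds an independent Poisson component of rate ``amplitude_hz``
    over ``[onset + latency, onset + latency + duration)`` (latency
    jittered per event by ``jitter_sd_ms``).  The expected post-onset
    excess count per event is amplitude x duration.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if events.onsets.size and (events.onsets.min() < 0 or
                               events.onsets.max() > span_ms):
        raise ValueError("events must lie within [0, span_ms]")
    parts = []
    n_base = rng.poisson(spec.baseline_rate_hz * span_ms / 1000.0)
    parts.append(rng.uniform(0.0, span_ms, size=n_base))
    if spec.amplitude_hz > 0:
        for on in events.onsets:
            lat = spec.latency_ms + (rng.normal(0, spec.jitter_sd_ms)
                                     if spec.jitter_sd_ms > 0 else 0.0)
            n_extra = rng.poisson(spec.amplitude_hz * spec.duration_ms / 1000.0)
            parts.append(on + lat + rng.uniform(0.0, spec.duration_ms, size=n_extra))
    times = np.sort(np.concatenate(parts))
    times = times[(times >= 0) & (times <= span_ms)]
    # enforce strict monotonicity (ties are measure-zero but possible in float)
    while times.size > 1 and np.any(np.diff(times) <= 0):
        dup = np.flatnonzero(np.diff(times) <= 0) + 1
        times[dup] = np.nextafter(times[dup - 1], np.inf)
        times = np.sort(times)
    return SpikeTrain(spike_times=times, recording_span=(0.0, span_ms))


def generate_noise_burst_events(n_events: int, span_ms: float,
                                burst_duration_ms: float = 50.0,
                                min_separation_ms: float = 2000.0,
                                seed: int | np.random.Generator | None = None
                                ) -> EventTimes:
    """Randomly timed 50 ms noise-burst events, separated enough that the
    +-1 s analysis windows around consecutive events stay disjoint."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    need = n_events * min_separation_ms + 2000.0
    if span_ms < need:
        raise ValueError(f"span_ms {span_ms} too short for {n_events} events "
                         f"at {min_separation_ms} ms separation (need {need})")
    slack = span_ms - 2000.0 - (n_events - 1) * min_separation_ms
    offsets = np.sort(rng.uniform(0.0, slack, size=n_events))
    onsets = 1000.0 + offsets + np.arange(n_events) * min_separation_ms
    return EventTimes(onsets=onsets, offsets=onsets + burst_duration_ms,
                      kind="noise_burst")


@dataclass(frozen=True)
class AntidromicSignal:
    """A damped post-stimulus oscillation: the evoked-response waveform."""

    freq_hz: float = 1000.0
    amplitude: float = 1.0
    onset_ms: float = 3.0
    decay_ms: float = 4.0


def generate_antidromic_trials(n_trials: int,
                               signal: AntidromicSignal | None = None,
                               noise_sd: float = 1.0,
                               sample_rate: float = 40_000.0,
                               trace_ms: float = 20.0,
                               stimulus_time_ms: float = 0.0,
                               seed: int | np.random.Generator | None = None
                               ) -> AntidromicTrialSet:
    """Gaussian-noise voltage traces with an optional damped sinusoid added
    after the stimulus, emulating evoked antidromic field responses."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(trace_ms * sample_rate / 1000.0))
    traces = rng.normal(0.0, noise_sd, size=(n_trials, n))
    if signal is not None:
        t_ms = np.arange(n) / sample_rate * 1000.0 - stimulus_time_ms
        rel = t_ms - signal.onset_ms
        if signal.onset_ms < 0 or signal.onset_ms > trace_ms:
            raise ValueError("signal onset outside trace span")
        wave = np.where(rel >= 0,
                        signal.amplitude * np.exp(-np.maximum(rel, 0) / signal.decay_ms)
                        * np.sin(2 * np.pi * signal.freq_hz * rel / 1000.0),
                        0.0)
        traces = traces + wave[None, :]
    return AntidromicTrialSet(traces=traces, sample_rate=sample_rate,
                              stimulus_time=stimulus_time_ms)
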