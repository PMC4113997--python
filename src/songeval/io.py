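"""Readers and writers for the plain-text formats the pipelines exchange.

WAV (mono PCM16 or float), TSV tables (UTF-8, '.' decimal, header row),
spike-time text files (one float ms per line), event tables, antidromic
trial matrices with a sample-rate header line, and JSON run manifests.
Every writer's output round-trips through the corresponding reader.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .audio_features import AudioClip, FeatureTrack, SyllableSeg
from .neural import AntidromicTrialSet, EventTimes, SpikeTrain


def read_wav(path: str | Path) -> AudioClip:
    """Read a mono WAV file; integer PCM is rescaled to [-1, 1]."""
    sr, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(f"{path}: stereo WAV not supported (got shape {data.shape})")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(float)
    return AudioClip(samples=data, sample_rate=float(sr))


def write_wav(path: str | Path, clip: AudioClip) -> None:
    x = np.clip(clip.samples, -1.0, 1.0)
    wavfile.write(path, int(clip.sample_rate), (x * 32767.0).astype(np.int16))


def read_segments(path: str | Path) -> list[SyllableSeg]:
    df = pd.read_csv(path, sep="\t")
    for col in ("onset_ms", "offset_ms"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    return [SyllableSeg(float(r.onset_ms), float(r.offset_ms))
            for r in df.itertuples()]


def write_segments(path: str | Path, segs: list[SyllableSeg]) -> None:
    pd.DataFrame({"onset_ms": [s.onset_ms for s in segs],
                  "offset_ms": [s.offset_ms for s in segs]}
                 ).to_csv(path, sep="\t", index=False)


def write_features(path: str | Path, track: FeatureTrack) -> None:
    pd.DataFrame({"time_ms": track.frame_times, "amplitude": track.amplitude,
                  "fm": track.fm, "wiener_entropy": track.wiener_entropy,
                  "pitch_goodness": track.pitch_goodness, "pitch": track.pitch,
                  "silent": track.silent.astype(int)}
                 ).to_csv(path, sep="\t", index=False)


def read_features(path: str | Path) -> FeatureTrack:
    df = pd.read_csv(path, sep="\t")
    return FeatureTrack(frame_times=df["time_ms"].to_numpy(),
                        amplitude=df["amplitude"].to_numpy(),
                        fm=df["fm"].to_numpy(),
                        wiener_entropy=df["wiener_entropy"].to_numpy(),
                        pitch_goodness=df["pitch_goodness"].to_numpy(),
                        pitch=df["pitch"].to_numpy(),
                        silent=df["silent"].to_numpy().astype(bool))


def read_spike_times(path: str | Path,
                     recording_span: tuple[float, float] | None = None) -> SpikeTrain:
    """One spike time (ms) per line; blank lines and '#' comments ignored."""
    times = []
    for ln, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        try:
            times.append(float(s))
        except ValueError as exc:
            raise ValueError(f"{path}:{ln}: not a number: {s!r}") from exc
    return SpikeTrain(spike_times=np.asarray(times), recording_span=recording_span)


def write_spike_times(path: str | Path, spikes: SpikeTrain) -> None:
    Path(path).write_text(
        "\n".join(f"{t:.6f}" for t in spikes.spike_times) + "\n", encoding="utf-8")


def read_events(path: str | Path) -> EventTimes:
    """TSV with onset_ms [, offset_ms, kind] columns."""
    df = pd.read_csv(path, sep="\t")
    if "onset_ms" not in df.columns:
        raise ValueError(f"{path}: missing required column 'onset_ms'")
    offsets = df["offset_ms"].to_numpy() if "offset_ms" in df.columns else None
    kind = str(df["kind"].iloc[0]) if "kind" in df.columns and len(df) else "noise_burst"
    return EventTimes(onsets=df["onset_ms"].to_numpy(), offsets=offsets, kind=kind)


def write_events(path: str | Path, events: EventTimes) -> None:
    data = {"onset_ms": events.onsets}
    if events.offsets is not None:
        data["offset_ms"] = events.offsets
    data["kind"] = [events.kind] * len(events.onsets)
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_antidromic_trials(path: str | Path) -> AntidromicTrialSet:
    """TSV voltage matrix (one trial per row) preceded by a header line
    ``# sample_rate_hz=<sr> stimulus_time_ms=<t>``."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or not lines[0].startswith("#"):
        raise ValueError(f"{path}: missing '# sample_rate_hz=...' header line")
    meta = dict(kv.split("=") for kv in lines[0].lstrip("# ").split())
    traces = np.loadtxt(lines[1:], delimiter="\t", ndmin=2)
    return AntidromicTrialSet(traces=traces,
                              sample_rate=float(meta["sample_rate_hz"]),
                              stimulus_time=float(meta.get("stimulus_time_ms", 0.0)))


def write_antidromic_trials(path: str | Path, ts: AntidromicTrialSet) -> None:
    header = f"# sample_rate_hz={ts.sample_rate:g} stimulus_time_ms={ts.stimulus_time:g}"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header + "\n")
        np.savetxt(fh, ts.traces, delimiter="\t", fmt="%.8g")


def write_manifest(path: str | Path, config: dict, seeds: dict | None = None,
                   counts: dict | None = None) -> None:
    """JSON run manifest: package version, resolved config + hash, seeds,
    per-stage counts (to make silent data loss visible)."""
    from . import __version__
    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {"songeval_version": __version__,
                "config": config,
                "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
                "seeds": seeds or {},
                "counts": counts or {}}
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n",
                          encoding="utf-8")
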