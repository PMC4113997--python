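"""Tutor-imitation scoring: acoustic similarity x sequence similarity.

The scoring procedure compares a pupil's song bouts against a segmented
tutor motif:

1. Both songs are reduced to per-frame acoustic features (FM, Wiener
   entropy, pitch goodness, pitch), z-scored against the tutor track.
2. A similarity matrix maps every (tutor frame, pupil frame) pair to
   ``exp(-d/tau)`` where ``d`` is the Euclidean feature distance.
3. The pupil bout — whose own segmentation is unreliable — is cut into
   sections of twice the tutor-motif duration, and each tutor syllable is
   matched against every diagonal placement within every section; the best
   placement gives the syllable's acoustic similarity.
4. A sequence score measures whether the song segments preceding and
   following each best-matched syllable also match the neighboring tutor
   syllables, i.e. whether syllables occur in the tutor's order.
5. The composite imitation score is the product of the duration-weighted
   acoustic score and the sequence score, averaged over bouts.

Imitation capacity rescales a composite score onto a linear scale spanning
the colony's dynamic range: from the mean pairwise similarity of unrelated
adult birds (floor) to the mean imitation score of intact tutored birds
(ceiling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .audio_features import FeatureTrack, SyllableSeg

DEFAULT_FEATURES = ("fm", "wiener_entropy", "pitch_goodness", "pitch")


@dataclass
class SimilarityMatrix:
    """Frame-by-frame similarity in [0, 1] between a tutor and a pupil track."""

    values: np.ndarray       # (n_tutor_frames, n_pupil_frames)
    frame_step_ms: float
    tau: float               # distance scale used in exp(-d/tau)


@dataclass
class TutorMotif:
    """A segmented tutor motif: feature track plus ordered syllables."""

    track: FeatureTrack
    syllables: list[SyllableSeg]
    duration_ms: float | None = None

    def __post_init__(self) -> None:
        if not self.syllables:
            raise ValueError("TutorMotif requires at least one syllable")
        if self.duration_ms is None:
            step = self.track.step_ms
            self.duration_ms = len(self.track) * step
        offs = [s.onset_ms for s in self.syllables]
        if offs != sorted(offs):
            raise ValueError("syllables must be time-ordered")


@dataclass
class SyllableMatch:
    tutor_syllable_index: int
    pupil_section_index: int
    pupil_offset_ms: float           # offset of the placement within its section
    acoustic_similarity: float
    sequence_similarity: float = np.nan
    pupil_frame: int = -1            # absolute pupil frame of the placement start


@dataclass
class ImitationResult:
    acoustic_score: float
    sequence_score: float
    imitation_score: float
    matches: list[list[SyllableMatch]] = field(default_factory=list)  # per bout
    n_bouts: int = 1
    single_syllable_flag: bool = False


@dataclass(frozen=True)
class CapacityScale:
    """Linear imitation-capacity scale anchored at colony reference scores.

    Defaults: control (intact tutored) birds average 0.197; pairwise
    comparisons of unrelated adults average 0.104, giving a dynamic range
    of 0.093.
    """

    control_mean: float = 0.197
    unrelated_mean: float = 0.104

    def __post_init__(self) -> None:
        if self.dynamic_range <= 0:
            raise ValueError("control_mean must exceed unrelated_mean")

    @property
    def dynamic_range(self) -> float:
        return self.control_mean - self.unrelated_mean


def _zscore_features(track: FeatureTrack, ref: FeatureTrack,
                     features: tuple[str, ...]) -> np.ndarray:
    ref_m = ref.feature_matrix(features)
    mu = ref_m.mean(axis=0)
    sd = np.maximum(ref_m.std(axis=0), 1e-8)
    return (track.feature_matrix(features) - mu) / sd


def build_similarity_matrix(tutor: FeatureTrack, pupil: FeatureTrack,
                            tau: float | None = None,
                            features: tuple[str, ...] = DEFAULT_FEATURES
                            ) -> SimilarityMatrix:
    """Similarity matrix S[i, j] = exp(-d(i, j)/tau) over z-scored features.

    Features are z-scored with the tutor track's statistics so Euclidean
    distance is unit-free.  ``tau`` defaults to the median pairwise
    distance among the tutor's own frames (the tutor track acting as the
    reference corpus), so the distance scale is fixed across all pupils
    compared against one tutor and scores stay comparable.
    """
    if len(tutor) == 0 or len(pupil) == 0:
        raise ValueError("similarity matrix requires non-empty tracks")
    zt = _zscore_features(tutor, tutor, features)
    zp = _zscore_features(pupil, tutor, features)
    d = cdist(zt, zp)
    if tau is None:
        dt = cdist(zt, zt)
        tau = float(np.median(dt[np.triu_indices_from(dt, k=1)]))
        if tau <= 0:
            tau = 1.0
    values = np.exp(-d / tau)
    return SimilarityMatrix(values=values, frame_step_ms=tutor.step_ms, tau=tau)


def section_pupil(n_pupil_frames: int, tutor_frames: int,
                  stride_frames: int | None = None) -> list[tuple[int, int]]:
    """Cut a pupil bout into sections of twice the tutor-motif duration.

    Sections advance by ``stride_frames`` (default one tutor-motif
    duration, i.e. 50% overlap); a final right-aligned section covers the
    bout end.  Returns ``[start, stop)`` frame index pairs.
    """
    sec_len = 2 * tutor_frames
    if n_pupil_frames < sec_len:
        raise ValueError(
            f"pupil bout of {n_pupil_frames} frames shorter than twice the "
            f"tutor motif ({sec_len} frames)")
    stride = stride_frames or tutor_frames
    starts = list(range(0, n_pupil_frames - sec_len + 1, stride))
    last = n_pupil_frames - sec_len
    if starts[-1] != last:
        starts.append(last)
    return [(s, s + sec_len) for s in starts]


def _syllable_frame_spans(motif: TutorMotif) -> list[tuple[int, int]]:
    step = motif.track.step_ms
    t0 = float(motif.track.frame_times[0])
    spans = []
    for syl in motif.syllables:
        a = int(round((syl.onset_ms - t0) / step))
        b = int(round((syl.offset_ms - t0) / step))
        a = max(0, a)
        b = min(len(motif.track), max(b, a + 1))
        spans.append((a, b))
    return spans


def _diagonal_scores(sim_block: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Mean similarity along each diagonal placement of a syllable block.

    ``sim_block`` is (L, S): rows are the syllable's tutor frames, columns a
    pupil section.  Returns an array of length S - L + 1 with, at offset o,
    the mean of ``sim_block[k, o + k]`` over pupil-valid frames (silent
    pupil frames excluded); 0 where no valid frame overlaps.
    """
    L, S = sim_block.shape
    n_off = S - L + 1
    if n_off <= 0:
        return np.empty(0)
    vals = np.stack([sim_block[k, k:k + n_off] for k in range(L)])      # (L, n_off)
    w = np.stack([valid[k:k + n_off] for k in range(L)]).astype(float)  # (L, n_off)
    wsum = w.sum(axis=0)
    with np.errstate(invalid="ignore"):
        out = np.where(wsum > 0, (vals * w).sum(axis=0) / np.maximum(wsum, 1), 0.0)
    return out


def match_syllables(motif: TutorMotif, sections: list[tuple[int, int]],
                    sim: SimilarityMatrix, pupil_valid: np.ndarray | None = None
                    ) -> tuple[float, list[SyllableMatch]]:
    """Best placement of every tutor syllable over all sections and offsets.

    A placement's score is the mean similarity along the aligned
    syllable-length diagonal; ties break to the earliest section, then the
    earliest offset.  The acoustic score is the duration-weighted mean of
    per-syllable best similarities.
    """
    if not sections:
        raise ValueError("match_syllables requires at least one section")
    if pupil_valid is None:
        pupil_valid = np.ones(sim.values.shape[1], dtype=bool)
    spans = _syllable_frame_spans(motif)
    step = sim.frame_step_ms
    matches: list[SyllableMatch] = []
    weights = []
    for i, (a, b) in enumerate(spans):
        best = (-np.inf, 0, 0)  # (score, section, offset) — first strict max wins
        for si, (c0, c1) in enumerate(sections):
            scores = _diagonal_scores(sim.values[a:b, c0:c1], pupil_valid[c0:c1])
            if scores.size == 0:
                continue
            o = int(np.argmax(scores))
            if scores[o] > best[0]:
                best = (float(scores[o]), si, o)
        if not np.isfinite(best[0]):
            raise ValueError(f"tutor syllable {i} longer than any pupil section")
        si, o = best[1], best[2]
        matches.append(SyllableMatch(
            tutor_syllable_index=i, pupil_section_index=si,
            pupil_offset_ms=o * step, acoustic_similarity=best[0],
            pupil_frame=sections[si][0] + o))
        weights.append(b - a)
    weights = np.asarray(weights, dtype=float)
    acoustic = float(np.sum(weights * [m.acoustic_similarity for m in matches])
                     / weights.sum())
    return acoustic, matches


def sequence_score(motif: TutorMotif, matches: list[SyllableMatch],
                   sim: SimilarityMatrix, pupil_valid: np.ndarray | None = None
                   ) -> float:
    """Sequence similarity: do the neighbors of each matched syllable match?

    For every matched tutor syllable, the preceding and following tutor
    syllables are scored against the pupil frames at the positions they
    would occupy if the pupil preserved the tutor's timing around the
    match.  The score is the mean over all defined neighbor comparisons;
    a single-syllable motif scores 1 by convention (no neighbors).
    """
    if len(matches) == 1:
        return 1.0
    if pupil_valid is None:
        pupil_valid = np.ones(sim.values.shape[1], dtype=bool)
    spans = _syllable_frame_spans(motif)
    n_pupil = sim.values.shape[1]
    scores = []
    for m in matches:
        i = m.tutor_syllable_index
        a_i = spans[i][0]
        for j in (i - 1, i + 1):
            if j < 0 or j >= len(spans):
                continue
            a_j, b_j = spans[j]
            # expected placement preserves the tutor-relative timing
            q = m.pupil_frame + (a_j - a_i)
            if q < 0 or q + (b_j - a_j) > n_pupil:
                continue  # neighbor comparison undefined at the bout edge
            L = b_j - a_j
            vals = sim.values[np.arange(a_j, b_j), np.arange(q, q + L)]
            w = pupil_valid[q:q + L]
            if w.sum() == 0:
                scores.append(0.0)
            else:
                scores.append(float(vals[w].mean()))
    return float(np.mean(scores)) if scores else 1.0


def score_bout(pupil: FeatureTrack, motif: TutorMotif,
               tau: float | None = None,
               features: tuple[str, ...] = DEFAULT_FEATURES,
               stride_frames: int | None = None
               ) -> tuple[float, float, list[SyllableMatch]]:
    """Acoustic and sequence scores of one pupil bout against the motif."""
    sim = build_similarity_matrix(motif.track, pupil, tau=tau, features=features)
    sections = section_pupil(len(pupil), len(motif.track), stride_frames)
    valid = ~pupil.silent
    acoustic, matches = match_syllables(motif, sections, sim, valid)
    seq = sequence_score(motif, matches, sim, valid)
    for m in matches:
        m.sequence_similarity = seq
    return acoustic, seq, matches


def imitation_score(pupil_bouts: list[FeatureTrack], motif: TutorMotif,
                    tau: float | None = None,
                    features: tuple[str, ...] = DEFAULT_FEATURES,
                    stride_frames: int | None = None) -> ImitationResult:
    """Composite tutor-imitation score over a set of pupil bouts.

    Acoustic and sequence scores are averaged (unweighted) over bouts; the
    imitation score is their product.  Bouts shorter than twice the motif
    are skipped; if none remain an error is raised.
    """
    acc_a, acc_s, all_matches = [], [], []
    for bout in pupil_bouts:
        try:
            a, s, m = score_bout(bout, motif, tau=tau, features=features,
                                 stride_frames=stride_frames)
        except ValueError:
            continue
        acc_a.append(a)
        acc_s.append(s)
        all_matches.append(m)
    if not acc_a:
        raise ValueError("no pupil bout is long enough to score "
                         "(each must span at least twice the tutor motif)")
    acoustic = float(np.mean(acc_a))
    seq = float(np.mean(acc_s))
    return ImitationResult(acoustic_score=acoustic, sequence_score=seq,
                           imitation_score=acoustic * seq, matches=all_matches,
                           n_bouts=len(acc_a),
                           single_syllable_flag=len(motif.syllables) == 1)


def motif_from_track(track: FeatureTrack, syllables: list[SyllableSeg] | None = None,
                     max_duration_ms: float | None = None) -> TutorMotif:
    """Build a TutorMotif from a track, optionally cropped to syllable bounds.

    If ``syllables`` is None they are derived with the default amplitude
    segmentation.  With ``max_duration_ms`` set, only syllables ending
    within that span are kept and the track is cropped just past the last
    one — used by :func:`self_similarity` to carve a reference motif out of
    a full bout.
    """
    from .audio_features import segment_syllables
    if syllables is None:
        syllables = segment_syllables(track)
    if not syllables:
        raise ValueError("no syllables found to build a motif from")
    if max_duration_ms is not None:
        kept = [s for s in syllables if s.offset_ms <= max_duration_ms]
        syllables = kept or syllables[:1]
    step = track.step_ms
    stop = min(len(track), int(np.ceil(syllables[-1].offset_ms / step)) + 1)
    cropped = FeatureTrack(
        frame_times=track.frame_times[:stop], amplitude=track.amplitude[:stop],
        fm=track.fm[:stop], wiener_entropy=track.wiener_entropy[:stop],
        pitch_goodness=track.pitch_goodness[:stop],
        pitch=track.pitch[:stop], silent=track.silent[:stop])
    return TutorMotif(track=cropped, syllables=syllables)


def self_similarity(bouts_a: list[FeatureTrack], bouts_b: list[FeatureTrack],
                    motif: TutorMotif | None = None,
                    motif_fraction: float = 1 / 3,
                    **kwargs) -> ImitationResult:
    """Score bouts_b against a reference motif carved from bouts_a.

    Uses the same algorithm as tutor imitation, with the reference bird's
    own song supplying the motif: by default the leading ``motif_fraction``
    of the first bout of ``bouts_a``, cropped to syllable boundaries.  Used
    to track song degradation (e.g. pre- vs post-surgery song) by scoring
    later song against earlier song; normalizing by the pre/pre score gives
    a degradation index of 1 for unchanged song.
    """
    if not bouts_a or not bouts_b:
        raise ValueError("self_similarity requires non-empty bout sets")
    if motif is None:
        ref = bouts_a[0]
        span = len(ref) * ref.step_ms * motif_fraction
        motif = motif_from_track(ref, max_duration_ms=span)
    return imitation_score(bouts_b, motif, **kwargs)


def imitation_capacity(score: float, scale: CapacityScale = CapacityScale()
                       ) -> tuple[float, float, bool]:
    """Rescale an imitation score to (capacity, loss) fractions.

    capacity = (score - unrelated_mean) / dynamic_range; loss = 1 - capacity.
    Values outside [0, 1] are returned unclipped; the third element flags
    whether the score fell inside the scale's dynamic range.
    """
    capacity = (score - scale.unrelated_mean) / scale.dynamic_range
    return capacity, 1.0 - capacity, 0.0 <= capacity <= 1.0
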