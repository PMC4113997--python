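import numpy as np
import pytest

from songeval import (AudioClip, FeatureTrack, TutorMotif, extract_features)
from songeval.synth import default_template, generate_tutor_motif_clip


@pytest.fixture(scope="session")
def template():
    return default_template()


@pytest.fixture(scope="session")
def tutor_motif(template):
    """Segmented tutor motif from a clean rendering of the default template."""
    clip, segs = generate_tutor_motif_clip(template)
    track = extract_features(clip)
    return TutorMotif(track=track, syllables=segs)


def make_track(features: np.ndarray, step_ms: float = 1.0,
               silent=None) -> FeatureTrack:
    """Build a FeatureTrack directly from an (n, 4) feature matrix
    (fm, wiener_entropy, pitch_goodness, pitch)."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    n = features.shape[0]
    return FeatureTrack(
        frame_times=np.arange(n) * step_ms + step_ms / 2,
        amplitude=np.zeros(n),
        fm=features[:, 0],
        wiener_entropy=features[:, 1],
        pitch_goodness=features[:, 2],
        pitch=features[:, 3],
        silent=np.zeros(n, dtype=bool) if silent is None else np.asarray(silent, bool),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
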