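"""Characterize a unit's response to noise-burst playback.

Simulates a Poisson unit with a known rectangular response (24 ms latency,
90 ms duration, +60 Hz over a 5 Hz baseline) to 50 ms noise bursts, then
runs the full response battery: paired window t-test, circular-shift
bootstrap on the PSTH peak, and latency/duration detection from 2 ms bins.
"""

import numpy as np

from songeval import characterize_response
from songeval.synth import (ResponseSpec, generate_noise_burst_events,
                            generate_spike_train)

rng = np.random.default_rng(1)
events = generate_noise_burst_events(100, 350_000, seed=rng)
spec = ResponseSpec(baseline_rate_hz=5.0, latency_ms=24.0,
                    amplitude_hz=60.0, duration_ms=90.0)
spikes = generate_spike_train(events, spec, span_ms=350_000, seed=rng)
print(f"{spikes.spike_times.size} spikes, {events.onsets.size} noise bursts")

stats = characterize_response(spikes, events, n_shuffles=1000, seed=2)
print(f"window test (150 ms pre vs post, paired t): p = {stats.window_test_p:.2e}")
print(f"circular-shift bootstrap on PSTH peak:      p = {stats.bootstrap_p:.4f} "
      f"(significant: {stats.significant})")
print(f"detected latency  : {stats.latency_ms:.0f} ms (injected 24 ms)")
print(f"detected duration : {stats.duration_ms:.0f} ms (injected 90 ms)")

# A responsive unit shows a tiny window-test p, a bootstrap p below 0.05
# (peak above the 95th percentile of 1000 circularly shifted surrogates),
# and recovered latency/duration close to the injected ground truth.
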