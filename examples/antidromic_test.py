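"""Significance of an antidromic response from evoked voltage traces.

Compares the 200 Hz - 2 kHz band power of stimulus-evoked traces in a
2-17 ms post-stimulus window against no-response reference recordings:
a site with a genuine antidromic volley (here a 1 kHz damped oscillation)
yields a tiny p, a silent site a p near uniform.
"""

from songeval import antidromic_significance, site_band_power
from songeval.synth import AntidromicSignal, generate_antidromic_trials

signal = AntidromicSignal(freq_hz=1000.0, amplitude=10.0, onset_ms=3.0,
                          decay_ms=4.0)
responding = generate_antidromic_trials(16, signal, noise_sd=1.0, seed=1)
silent = generate_antidromic_trials(16, None, noise_sd=1.0, seed=2)
reference = generate_antidromic_trials(16, None, noise_sd=1.0, seed=3)

for label, site in (("responding site", responding), ("silent site", silent)):
    p = antidromic_significance(site, reference)
    bp = site_band_power(site)
    print(f"{label}: averaged-trace band power {bp:.4g}, one-sided t-test "
          f"p = {p:.4g}")

# The responding site's evoked oscillation concentrates power in the
# 200 Hz - 2 kHz band, separating it sharply from the no-response
# reference; the silent site is statistically indistinguishable from it.
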