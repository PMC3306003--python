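"""The 1/N_delta noise-suppression law of impulse-train correlation.

Averaging a noisy period-3 waveform at every third sample (one impulse
train phase) estimates the clean signal value; the estimator's variance
shrinks inversely with the number of impulses N_delta.
"""

import numpy as np

from exonscan import make_noisy_periodic, periodic_template

period, sd, trials = 3, 1.0, 500
s0 = periodic_template(period, period)[0]

print(f"{'N_delta':>8} {'empirical var':>14} {'sd^2/N_delta':>14}")
for n_delta in (30, 90, 270):
    errs = []
    for t in range(trials):
        x = make_noisy_periodic(period, n_delta * period, sd, seed=1000 * n_delta + t)
        errs.append(x[0::period][:n_delta].mean() - s0)
    print(f"{n_delta:>8} {np.var(errs):>14.5f} {sd**2 / n_delta:>14.5f}")

print("\nThe empirical variance of the correlation estimate tracks the"
      "\npredicted sigma^2 / N_delta: tripling the impulse count cuts the"
      "\nnoise variance by three while the periodic signal is untouched.")
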