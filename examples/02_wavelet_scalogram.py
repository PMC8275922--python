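"""Inspect the normalized Morlet wavelet power of a spike-and-wave train.

Computes the variance-normalized scalogram of a short synthetic seizure and
prints the power the detector thresholds: the slow-wave rows (2.7 / 3.3 Hz,
threshold T_E = 0.05) ride far above threshold during the discharge, while
the spike row (15.3 Hz, threshold T_S = 0.012) pulses once per cycle.
"""

import numpy as np

from swdetect import MorletSpec, SynthConfig, TimeSeries, gen_background, gen_swd
from swdetect.cwt import power_at

fs = 250.0
cfg = SynthConfig()
bg = gen_background(20.0, fs, rms=30.0, seed=8)
swd = gen_swd(8.0, fs, cfg)
x = bg.samples.copy()
x[int(6 * fs):int(6 * fs) + len(swd)] += swd.samples
trace = TimeSeries(x, fs, "Fp1-T3")

pm = power_at(trace, [2.7, 3.3, 15.3], MorletSpec(fc=1.0))
inside = slice(int(7 * fs), int(13 * fs))
outside = slice(int(0 * fs), int(5 * fs))
print(f"buffer variance sigma^2 = {pm.variance:.0f} uV^2")
for f in (2.7, 3.3, 15.3):
    w = pm.row(f)
    print(f"w({f:>4} Hz): median in-seizure {np.median(w[inside]):.4f}   "
          f"median background {np.median(w[outside]):.4f}")
print("\nspike-band pulsatility (what the variance check measures):")
print(f"  var(w(15.3)) in-seizure  {np.var(pm.row(15.3)[inside]):.2e}")
print(f"  var(w(15.3)) background  {np.var(pm.row(15.3)[outside]):.2e}")
print("\nThe slow-wave rows sit two orders of magnitude above the envelope "
      "threshold T_E=0.05 during the discharge and far below it outside; the "
      "spike row carries several-fold more power, and much more variance, "
      "inside the seizure than over background. Note that sigma^2 is the "
      "variance of the whole analyzed buffer, so a seizure-rich buffer "
      "deflates every normalized power value.")
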