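"""Hjorth descriptors of simple signals.

Activity is the variance, mobility approximates the (angular) mean frequency
per sample, and complexity compares the signal's bandwidth to a pure sine
(complexity = 1 in the sine limit).
"""

import numpy as np

from cchp.hjorth import activity, complexity, mobility

fs = 128.0
t = np.arange(int(30 * fs)) / fs
sine = 2.0 * np.sin(2 * np.pi * 5 * t)
noise = np.random.default_rng(0).standard_normal(t.size)

for name, x in [("5 Hz sine (amplitude 2)", sine), ("white noise", noise)]:
    print(
        f"{name:24s} activity={activity(x):7.3f}  "
        f"mobility={mobility(x):6.4f}  complexity={complexity(x):6.3f}"
    )

print()
print(f"sine: activity ~ a^2/2 = {2.0**2 / 2}; mobility ~ 2*pi*f/fs = {2*np.pi*5/fs:.4f}")
print("noise: complexity well above 1 (broadband), mobility near its white-noise limit")
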