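"""Extract linear laws of simple series and verify their defining properties.

A linear law is the unit vector v minimising ||A v|| over the time-delay
embedding A of a series; its residual is that minimum, the smallest
eigenvalue of S = A'A.  A residual of ~0 means the series obeys an exact
linear recurrence with coefficients v.
"""

import numpy as np

from linlaw import embed, law_of_series

t = np.arange(1.0, 101.0)

ramp = law_of_series(3 * t + 7, order=3)
print("ramp 3t+7, order 3")
print("  coefficients:", np.round(ramp.coefficients, 4))
print("  residual:    ", f"{ramp.residual:.2e}")
print("  -> proportional to (1,-2,1)/sqrt(6): the second difference of any")
print("     arithmetic progression vanishes, whatever its slope or offset.")

wave = law_of_series(np.sin(np.pi * t / 2), order=3)
print("\nperiod-4 sinusoid, order 3")
print("  coefficients:", np.round(wave.coefficients, 4))
print("  residual:    ", f"{wave.residual:.2e}")
print("  -> (1,0,1)/sqrt(2): this sinusoid satisfies z_{t+2} = -z_t.")

z = np.random.default_rng(0).normal(size=100)
a, b = law_of_series(z, 5), law_of_series(10 * z, 5)
print("\namplitude scaling (x10) of a random series, order 5")
print("  max coefficient change:", f"{np.abs(a.coefficients - b.coefficients).max():.2e}")
print("  residual ratio:        ", f"{b.residual / a.residual:.1f}  (= 10^2)")
print("  -> laws are amplitude-invariant; residuals scale with power.")

A = embed(z, 5)
Av = A @ a.coefficients
print("\nresidual equals ||A v||^2:",
      f"{a.residual:.6f} vs {float(Av @ Av):.6f}")
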