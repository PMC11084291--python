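"""Grid-convergence (Richardson/GCI) analysis of a refinement study.

A three-grid study of a quantity converging at second order is analysed:
the observed order, extrapolated zero-spacing value, pairwise error and
GCI, and the asymptotic-range check are reported. An oscillatory triplet
shows the non-monotone flag.
"""

import numpy as np

import graftflow as gf

# constructed second-order study: f = f* + C h^2 on h = 1, 2, 4 (x 1e-4 m)
h = np.array([1e-4, 2e-4, 4e-4])
f = 22.0 + 3.0e6 * h**2

res = gf.gci_study(gf.GridStudy(h=h, f=f))
print(f"observed order p     : {res.p:.3f} (constructed: 2)")
print(f"extrapolated value   : {res.f_ext:.3f} (constructed limit: 22)")
print(f"E (21, 32)           : {res.E[0]:.3e}, {res.E[1]:.3e}")
print(f"GCI% (21, 32)        : {res.gci[0]:.3f}, {res.gci[1]:.3f}")
print(f"asymptotic ratio     : {res.asymptotic_ratio:.3f} (~1 is asymptotic)")

# oscillatory convergence: the medium grid overshoots the bracket
est = gf.observed_order(1.000, 1.010, 0.995, r21=2.0, r32=2.0)
print(f"\noscillatory triplet  : monotone={est.monotone}, "
      f"effective order {est.p:.2f}")
print("non-monotone convergence is flagged instead of silently reported;")
print("a GCI built on such an order is not meaningful.")
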