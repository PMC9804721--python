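"""Bifurcation structure with a thermally sensitive logistic resource.

Sweeping temperature for three consumer half-saturation constants: the
efficient consumer (R_0 = 0.5) destabilises the equilibrium over a window
bounded by two Hopf bifurcations (predator-prey cycles); moderate and
prudent consumers (R_0 = 1, 2) stay on stable equilibria everywhere.
"""

import numpy as np

from thermoniche import cycle_summary, get_fixture, logistic_branch_scan

T = np.arange(0.0, 40.0, 0.05)
for name in ("fig3_r05", "fig3_r1", "fig3_r2"):
    fx = get_fixture(name)
    cp, rt = fx["consumer"], fx["resource"]
    branch = logistic_branch_scan(T, cp, rt)
    tc = branch.bifurcation_temperatures("transcritical")
    hp = branch.bifurcation_temperatures("hopf")
    print(f"R_0={cp.R_0}: transcriticals at {', '.join(f'{t:.2f}' for t in sorted(tc))}")
    print(f"         Hopf points: {', '.join(f'{t:.3f}' for t in hp) or 'none'}")

fx = get_fixture("fig3_r05")
cs = cycle_summary("logistic", 25.0, fx["consumer"], fx["resource"])
print(f"\nlimit cycle at T=25, R_0=0.5: R in [{cs.R_min:.3f}, {cs.R_max:.3f}], "
      f"C in [{cs.C_min:.3f}, {cs.C_max:.3f}], period ~ {cs.period:.1f}")
print("the cycle brackets the unstable equilibrium — enrichment-driven "
      "oscillations selected by temperature.")
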