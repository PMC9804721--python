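"""Diagnosing the metabolic-meltdown configuration.

Without mismatch, resources rebound as warming pushes the consumer toward
its realized Tmax (top-down control relaxes).  With a strongly
colder-adapted resource the realized Tmax moves onto the negative-sloping
flank of the consumer's ZNGI: resource density then *declines* with warming
near the upper limit — warming and starvation compound.
"""

from thermoniche import get_fixture, meltdown_report, rstar

for name in ("fig4", "fig5b", "meltdown_calibrated"):
    fx = get_fixture(name)
    cp, rt = fx["consumer"], fx["resource"]
    rep = meltdown_report(cp, rt)
    slope = "declining" if rep.slope_at_tmax < 0 else "rising"
    print(f"{name} (delta_T={rt.delta_T:+.0f}):")
    print(f"  realized niche {rep.t_min:.2f} .. {rep.t_max:.2f} degC "
          f"(ZNGI minimum at {rep.zngi_min_T:.2f})")
    print(f"  Tmax limited by: {rep.limiting_factor_tmax}; "
          f"R* {slope} toward Tmax; meltdown = {rep.meltdown}")
    R_near = rstar(rep.t_max - 0.5, cp)
    print(f"  equilibrium resource 0.5 degC below realized Tmax: {R_near:.3f}\n")
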