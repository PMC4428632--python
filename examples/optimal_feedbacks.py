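"""Construct the information-optimal feedback curves.

Builds the closed-form optimal internal feedback (self-regulation profile)
and external feedback (autoinducer output rate) for both regulation models
and prints their boundary behavior plus the optimal small-noise information.
"""

import numpy as np

import qscensus as qs

params = qs.QSParameters.table1()

for kind in ("tf", "srna"):
    sol = qs.optimal_solution(params, kind)
    m = np.linspace(params.m_minus, params.m_plus, 5)
    print(f"--- {kind.upper()} regulation ---")
    print("m (nM)         :", "  ".join(f"{x:7.1f}" for x in m))
    print("f_int*(m)      :", "  ".join(f"{x:7.3f}" for x in sol.f_int_star(m)))
    print("f_ext*(m)/f_-  :", "  ".join(
        f"{x:7.2f}" for x in sol.f_ext_star(m) / sol.f_ext_scale))
    print(f"optimal small-noise MI: {sol.I_star_smallnoise:.3f} bits")
    print()

print("f_int* starts at the measured self-induction level (2) and ends at the")
print("self-repression level (1/2).  For TF regulation it first rises (positive")
print("feedback skips the noisy low-abundance regime); for sRNA regulation it")
print("decreases throughout, damping noise.  f_ext* reshapes the autoinducer")
print("time course so detection stays near the Hill constant K.")
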