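"""Reproduce the headline information table.

Computes the exact mutual information between cell density and monitor
protein abundance for both regulation models (TF and sRNA), with and without
feedbacks, at the built-in preset parameters.
"""

import qscensus as qs

params = qs.QSParameters.table1()

print("regulation  feedback   MI (bits)  states")
for kind in ("tf", "srna"):
    base = qs.no_feedback_baseline(params, kind)
    opt = qs.optimal_solution(params, kind)
    for label, sol in (("none", base), ("optimal", opt)):
        channel = qs.build_channel(sol.maps, sol.stats)
        mi = qs.numerical_mi(channel).value
        lo, hi = qs.distinguishable_states(mi)
        states = str(lo) if lo == hi else f"{lo}-{hi}"
        print(f"{kind:10s}  {label:9s}  {mi:8.3f}  {states}")

print()
print("Each MI value is the number of bits a single cell can learn about its")
print("colony's density from one readout of the monitor protein; 2^MI is the")
print("number of density ranges it can tell apart.  Self-repression pays off")
print("for sRNA regulation (about +0.7 bits) but not for TF regulation.")
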