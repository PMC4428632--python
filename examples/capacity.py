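"""Channel capacity versus the information actually transmitted.

Compares three quantities on the optimal-feedback sRNA channel: the
small-noise capacity (1-D integral over the channel resolution), the exact
mutual information under the growth-induced 1/rho input, and the exact
capacity of the discretized channel from the Blahut-Arimoto algorithm.
"""

import qscensus as qs

params = qs.QSParameters.table1()
sol = qs.optimal_solution(params, "srna")

small_noise = qs.small_noise_capacity(sol.maps, sol.stats)
channel = qs.build_channel(sol.maps, sol.stats)
mi = qs.numerical_mi(channel)
cap = qs.blahut_arimoto(channel, tol=1e-4, max_iter=100_000)

print(f"small-noise capacity          : {small_noise.value:.3f} bits")
print(f"exact MI, 1/rho input         : {mi.value:.3f} bits")
print(f"Blahut-Arimoto capacity       : {cap.value:.3f} bits "
      f"({cap.diagnostics['iterations']} iterations)")
print()
print("The optimal external feedback makes 1/rho the capacity-achieving input")
print("of the small-noise theory, so the first two numbers bracket how much")
print("of the theoretical budget growth actually uses.  The exact capacity")
print("sits above both: at burst size b = 20 the Gaussian noise is not small,")
print("and boundary effects let carefully chosen inputs carry a little more.")
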