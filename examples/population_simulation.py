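"""Stochastic simulation of a colony against the linearized predictions.

Simulates 200 cells at a fixed density with an inverse self-repression
feedback (f_int proportional to 1/m) and checks the stationary Fano factor
against the feedback prediction F* = F/2.
"""

import numpy as np

import qscensus as qs
from qscensus.dynamics import FeedbackCurve, FeedbackPair

params = qs.QSParameters.table1()
base = qs.no_feedback_baseline(params, "tf")
rho = float(np.sqrt(params.rho_minus * params.rho_plus))
_, m0 = qs.solve_fixed_point(params, base.rate, base.feedbacks, rho)

feedbacks = FeedbackPair(
    f_ext=base.feedbacks.f_ext,
    f_int=FeedbackCurve.power_law(-1.0, m0),
)
ens = qs.simulate_population(
    params, base.rate, feedbacks, base.model,
    mode="fixed_density", rho=rho, N=200, t_max=50 * params.tau_m,
    seed=42, record_every=5,
)
stats = qs.ensemble_statistics(ens, burn_in=10 * params.tau_m)

bare = (1 + params.b) / params.v
print(f"fixed point             : {m0:.1f} nM")
print(f"ensemble mean           : {stats.mean:.1f} +- {stats.se_mean:.1f} nM")
print(f"stationary Fano factor  : {stats.fano:.1f} (predicted {bare / 2:.1f}, "
      f"bare {bare:.0f})")
print(f"correlation time        : {stats.tau_est:.0f} s "
      f"(predicted {params.tau_m / 2:.0f} s)")
print()
print("Negative self-regulation halves both the expression noise (Fano) and")
print("the response time relative to the feedback-free channel, which is how")
print("internal feedback buys information without changing the mean response.")
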