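"""Joint state-parameter estimation on the toy model (twin experiment).

Synthetic noisy density snapshots are generated at known rates
(mu = 0.08/yr, lambda = 0.2/yr); the augmented ensemble Kalman filter
then re-estimates both rates from the data alone.  A reduced ensemble
and age grid keep this example fast; the reference configuration
(M = 500, 1000 age cells) is exercised by the tests and the acceptance
script.
"""

from agemort import AgeTimeGrid
from agemort.experiments import run_toy_twin

grid = AgeTimeGrid(a_max=120.0, n_age=300, delta_t=0.1, n_time=100)
result = run_toy_twin(seed=0, m=100, grid=grid)

print("time   mu_hat   lam_hat   (truth: 0.0800, 0.2000)")
for t in (0.5, 1.0, 2.0, 5.0, 10.0):
    k = int(round(t / grid.delta_t))
    print(f"{t:4.1f}   {result.mu_hat[k]:.4f}   {result.lam_hat[k]:.4f}")

print(
    f"\nlambda locks into a 10% band at t = "
    f"{result.convergence_time('lam'):.1f} yr; "
    f"mu at t = {result.convergence_time('mu'):.1f} yr."
)
print(
    "The influx-shape rate is identified quickly from the age profile;"
    "\nthe mortality rate needs several years of decay signal."
)
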