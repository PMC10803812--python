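"""Simulate a reactor ICC series and recover the NGTR that generated it.

Forward-integrates the CSTR number balance with a tenfold NGTR step at
day 5 (the kind of shift elevated influent water age produces), samples
it noise-free, and checks that the non-steady-state estimator recovers
the true rate in each segment.
"""

from aquage import ngtr_nonsteady
from aquage.synthetic import (
    SeriesScenario,
    piecewise_constant,
    simulate_reactor_series,
)

scenario = SeriesScenario(
    duration_days=10.0,
    sample_interval_days=0.01,
    ngtr_profile=piecewise_constant([0.0, 5.0], [5e7, 5e8]),
    biofilm_accum_profile=0.0,
    noise_gcv=0.0,
    biofilm_sample_days=[0.0, 5.0, 10.0],
    seed=1,
)
sim = simulate_reactor_series(scenario)
bf = {b.day: b for b in sim.biofilm}

for t1, t2 in ((0.0, 5.0), (5.0, 10.0)):
    est = ngtr_nonsteady(sim.bulk, bf[t1], bf[t2], scenario.config)
    truth = sim.truth.mean_ngtr(t1, t2)
    err = abs(est.ngtr - truth) / truth
    print(f"window ({t1:g}, {t2:g}] d: NSS NGTR = {est.ngtr:.3e} cells/day, "
          f"truth = {truth:.3e}, error = {err:.2%}")

# Sub-percent recovery on noise-free input shows the estimator is exact
# up to time discretization; with real (noisy, sparse) sampling the error
# budget is dominated by measurement noise, not the balance itself.
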