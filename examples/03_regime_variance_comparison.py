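"""Compare intrapopulation trait variance between Slow and Fast regimes.

Runs a small ensemble per deterministic regime, collects the endpoint
variance of the maturation rate within each surviving population, and
tests Slow > Fast with Welch's t-test on the log variances.  Slower cycles
let more life-history strategies coexist, so Slow populations keep higher
variance.
"""

import numpy as np

from tigrisim import (
    SimulationConfig,
    VarianceSample,
    ensemble_endpoint_variances,
    run_ensemble,
    welch_log_variance_test,
)

ensembles = {}
for label, period in (("Fast", 3), ("Slow", 14)):
    config = SimulationConfig(regime="deterministic", period=period,
                              scale_factor=0.1, horizon=150)
    ensembles[label] = run_ensemble(config, n_realisations=10, master_seed=1)

variances = {label: ensemble_endpoint_variances(trajs, "mu")
             for label, trajs in ensembles.items()}
for label, v in variances.items():
    print(f"{label}: {np.sum(np.isfinite(v))}/10 populations survive, "
          f"mean endpoint var(mu) = {np.nanmean(v):.3g}")

t, df, p = welch_log_variance_test(
    VarianceSample("Slow", variances["Slow"]),
    VarianceSample("Fast", variances["Fast"]))
print(f"Welch on log variances (Slow vs Fast): t = {t:.2f}, "
      f"df = {df:.1f}, p = {p:.2g}")
print("t > 0 with small p: Slow maintains significantly more variation.")
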