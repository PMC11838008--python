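"""Calibrate kinetic parameters against a noisy replicate campaign.

Generates a 7-time-point, 3-replicate dataset at 2% CV from known
parameters, then re-estimates two key parameters by weighted maximum
likelihood from deliberately wrong starting values.
"""

import fermflux as ff

truth = ff.preset_parameters("fast")
dataset, _ = ff.generate_dataset(
    truth, ff.synthetic_must(),
    ff.SamplingDesign(seed=42, cv=0.02,
                      observables=("X", "Glx", "F", "Eth")))

start = truth.with_values({"vmax_glx": 1.2, "y_eth": 0.55})
config = ff.ModelConfiguration(name="demo", params=start,
                               estimable=("vmax_glx", "y_eth"))
result = ff.fit(dataset, config, ff.OptimizerSettings(seed=1, n_starts=2))
half = ff.confidence_intervals(result, dataset)
r2 = ff.r_squared(result, dataset)

print(f"weighted cost at optimum: {result.cost:.2f} "
      f"over {result.n_points} data points")
for name in config.estimable:
    est, ref = result.theta_hat.get(name), truth.get(name)
    print(f"  {name:10s} estimate {est:.4f} +/- {half[name]:.4f} "
          f"(truth {ref:.4f})")
print("per-observable R^2:",
      {k: round(v, 4) for k, v in r2.items()})
print("Estimates should sit within their half-widths of the generating "
      "values; R^2 near 1 means the model tracks every observable.")
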