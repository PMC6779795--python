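"""Environment-repeat predictability and its decay with interval.

Selects same-environment scan-day pairs (skipping pairs whose box was
reused in between), predicts the later exposure from the earlier one
plus three shuffled control days, and regresses the across-location
mean relative error on the repeat interval.  A positive slope rho_m is
the signature of memory decay: the longer ago the environment was seen,
the less faithfully its pattern reactivates.
"""

import cortexdyn as cd

schedule = cd.demo_schedule(n_scans=12)
pairs = cd.select_repeat_pairs(schedule)
print("selected repeat pairs:")
for p in pairs:
    print(f"  {p.environment}: day {p.earlier_day} -> {p.later_day} (Inv = {p.interval})")

spec = cd.DynamicsSpec(
    "shared_recency", env_effect_scale=1.0, env_decay_rate=0.015, noise_sd=0.3
)
panels, _ = cd.generate_cohort(3, 500, schedule, {"II/III": spec}, seed=5)

results = {
    pair: [
        cd.run_repeat_prediction(p, pair, schedule, n_repeats=10, seed=40)
        for p in panels
    ]
    for pair in pairs
}
ordered, means, sds = cd.summarize_across_locations(results)
summary = cd.fit_interval_dependence(ordered, means, sds)

print("\nper-pair relative error (smaller = better reactivation):")
for p, m, s in zip(ordered, means, sds):
    print(f"  Inv {p.interval:3d} d ({p.environment}): "
          f"mean delta_r = {m:.3f}, sd across locations = {s:.3f}")
print(f"\nlinear fits: mean delta_r = {summary.rho_m:.4f}*Inv + {summary.alpha_m:.3f} "
      f"(R^2 = {summary.r2_m:.2f})")
print(f"             sd delta_r   = {summary.rho_s:.5f}*Inv + {summary.alpha_s:.3f} "
      f"(R^2 = {summary.r2_s:.2f})")
print(f"\nThe generator decays pattern fidelity by {spec.env_decay_rate}/day, "
      "and the fitted positive slope recovers that decay: predictability of a "
      "repeated environment falls with the time since the previous exposure.")
top = cd.most_repeated_environments(pairs)
print(f"most-repeated environments in this protocol: {top}")
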