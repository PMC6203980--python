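"""Trait-biomechanics statistics on a simulated two-variety cohort.

Simulates two phantom groups with different rind bundle densities, runs
the full pipeline on each slice, attaches a bending strength generated as
BS = 10 + 5*TA + noise, and then runs the statistics stage: the
correlation screen and stepwise-AIC regression rediscover TA as the
dominant predictor with a slope near 5 (AIC may retain weak extra terms,
as it is designed to trade a small overfit risk for predictive fit).
"""

import stalksect as ss

sparse = ss.PhantomSpec(
    section_axes_px=(170.0, 140.0), epidermis_thickness_px=8.0,
    n_rind_bundles=20, n_pith_bundles=15,
    rind_bundle_radius_px=(4.0, 5.5), pith_bundle_radius_px=(6.0, 9.0),
)
dense = ss.PhantomSpec(**{**sparse.__dict__, "n_rind_bundles": 35})

cohort = ss.generate_cohort(
    sparse, dense, n_per_group=6,
    mech_model={"intercept": 10.0, "coefs": {"TA": 5.0}, "noise_sd": 0.10},
    seed=11,
)
print(f"cohort: {len(cohort)} slices; group mean PVB:")
print(cohort.groupby("group")["PVB"].mean().to_string())

screen = ss.correlation_screen(cohort)
top = screen.sort_values("p").head(5)
print("\ntop correlations with bending strength:")
print(top.to_string(index=False, float_format="%.4g"))

model = ss.stepwise_aic(cohort, ["TA", "PAD", "AAD", "AR"])
print(f"\nstepwise-AIC selected: BS ~ {' + '.join(model.predictors)}")
print(model.summary_text())
print(
    "\nThe TA slope estimates the generative coefficient (5) and dwarfs any"
    "\nretained decoy terms; R^2 near 1 reflects the small injected noise."
)
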