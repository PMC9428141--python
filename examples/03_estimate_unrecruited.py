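"""Statistical gap estimation: Poisson regression plus Monte Carlo intervals.

A Poisson GLM of recruited count on ln(population), fitted to the reference
counties only, predicts the expected count of every county.  For target
counties, max(expected - recruited, 0) is the estimated number of
unrecruited cases; 10,000 coefficient draws give the empirical 95% interval.
"""

import registrygap as rg
from registrygap.pipeline import RunConfig, select_references

scenario = rg.generate_scenario(rg.ScenarioConfig(seed=42))
female = [r for r in scenario.records if r.stratum == "female"]

_, consensus = select_references(female, RunConfig())
rates = rg.compute_rates(female)
targets = {r.county_id for r in rates if r.rate < consensus.lower}
reference = [r for r in female if r.county_id in consensus.members]

fit = rg.fit_poisson(reference)
print(
    f"ln(population) coefficient {fit.b1:.4f} (SE {fit.se_b1:.4f}), "
    f"intercept {fit.b0:.4f}"
)
print(
    f"null deviance {fit.null_deviance:.4f} on {fit.df_null} df, "
    f"residual {fit.residual_deviance:.4f} on {fit.df_resid} df, AIC {fit.aic:.3f}"
)

estimates = rg.predict_expected(fit, female, targets)
intervals = rg.monte_carlo_interval(
    estimates, "per_stratum_total", n_draws=10_000, seed=42, fits={"female": fit}
)
iv = intervals["female"]
print(
    f"\nestimated unrecruited female cases: {iv.point:.2f} "
    f"[95% CI {iv.lower:.2f}, {iv.upper:.2f}]"
)
truth = scenario.truth
print(
    "planted truth:",
    truth[truth.stratum == "female"].missing.sum(),
    "missing female cases",
)

# A slope near 1 means case counts scale proportionally with population, as
# a homogeneous per-capita risk implies.
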