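"""Identify reference counties on the ranked incidence-rate series.

Three exploratory methods delimit the "normal" middle band of the ranked
recruited-case rate series -- a z-score band around the mean, the longest
flat (straight) section, and the Jenks natural-breaks section containing the
mean -- and a consensus combines them.  Counties below the band are the
target counties suspected of under-recruitment.
"""

import registrygap as rg
from registrygap.pipeline import RunConfig, select_references

scenario = rg.generate_scenario(rg.ScenarioConfig(seed=42))
female = [r for r in scenario.records if r.stratum == "female"]

ranges, consensus = select_references(female, RunConfig())

print(f"{'method':>18} {'z':>5} {'lower':>8} {'upper':>8} {'members':>8}")
for r in list(ranges) + [consensus]:
    z = f"{r.z_level:.2f}" if r.z_level else ""
    print(f"{r.method:>18} {z:>5} {r.lower:8.4f} {r.upper:8.4f} {len(r.members):8d}")

rates = rg.compute_rates(female)
targets = [r.county_id for r in rates if r.rate < consensus.lower]
print(f"\ntarget counties (rate below {consensus.lower:.4f}): {len(targets)}")

# Reference counties anchor the case~population model; every county ranked
# below the consensus band is treated as potentially under-ascertained.
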