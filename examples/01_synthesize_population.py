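"""Synthesize a household population and inspect its age/sex structure.

Households are drawn type-first from the census-calibrated default
specification (20 household types: singles, couples with and without
children, lone parents, student and other households), then composed
member by member.  The marginals table shows, per age/sex band, the share
of individuals in the band and the share of households containing at
least one such member - the quantities that drive service eligibility.
"""

from crcisim import load_demographic_spec, population_marginals, sample_households

spec = load_demographic_spec()
households = sample_households(spec, n=20_000, seed=1)

print(f"sampled {len(households):,} households, "
      f"{sum(h.size for h in households):,} people "
      f"(mean size {sum(h.size for h in households) / len(households):.2f})")

marginals = population_marginals(households)
marginals["individual_share"] = (100 * marginals["individual_share"]).round(1)
marginals["household_share"] = (100 * marginals["household_share"]).round(1)
print(marginals.rename(columns={"individual_share": "% of people",
                                "household_share": "% of households"}).to_string(index=False))
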