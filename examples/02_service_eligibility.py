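"""Who is eligible for what: the service registry in action.

The registry encodes each preventive service's age band, sex filter, risk
requirement, screening interval and baseline uptake rate.  A middle-aged
man is eligible for nothing unless he smokes, is diabetic or is otherwise
at risk for influenza; a 67-year-old woman is always due the age-based flu
vaccination, while 2-3 yearly cancer screening is due with the annual
eligibility fraction (schedule share + new entrants + past non-attenders).
"""

from crcisim import annual_eligibility_fraction, default_registry, eligible_services
from crcisim.types import Person

registry = default_registry()
print(f"{len(registry)} services in the registry; "
      f"{sum(s.included_in_crci for s in registry)} count toward the composite score")

for label, person in [
    ("67-year-old woman", Person(age=67, sex="female")),
    ("40-year-old man", Person(age=40, sex="male")),
    ("40-year-old male smoker", Person(age=40, sex="male", smoker=True)),
    ("pregnant 28-year-old", Person(age=28, sex="female", pregnant=True)),
]:
    records = eligible_services(person, registry, seed=0)
    names = ", ".join(r.service for r in records) or "(nothing)"
    print(f"  {label:26s} -> {names}")

p = annual_eligibility_fraction(k=3, f_new=1 / 45, r=0.765)
print(f"\ncervical screening (3-yearly, uptake 76.5%): "
      f"{100 * p:.1f}% of the age band is due it in any single year")
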