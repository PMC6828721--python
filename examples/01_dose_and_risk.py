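"""Deterministic dose and risk arithmetic for one water sample.

Evaluates the chronic daily intake of lead for a resident adult drinking
water at 56 µg/L, then the hazard quotient (dose over reference dose) and,
for nickel, the lifetime cancer risk (dose times slope factor).
"""

from aquarisk.exposure import (
    cdi_dermal,
    cdi_ingestion,
    default_adult_profile,
    default_toxicity,
    hazard_quotient,
    lifetime_cancer_risk,
)

adult = default_adult_profile().noncarcinogenic()
tox = default_toxicity()

dose = cdi_ingestion(56.0, adult, metal="Pb")
print(f"Pb ingestion CDI at 56 ug/L        : {dose.cdi:.5f} ug/kg/day")
print(f"Pb hazard quotient                 : {hazard_quotient(dose, tox):.4f}")

derm = cdi_dermal(56.0, adult, metal="Pb")
print(f"Pb dermal CDI                      : {derm.cdi:.6f} ug/kg/day")

ni_dose = cdi_ingestion(10.0, default_adult_profile().carcinogenic(), metal="Ni")
ltcr, label = lifetime_cancer_risk(ni_dose, tox)
print(f"Ni lifetime cancer risk at 10 ug/L : {ltcr:.3e} ({label})")

# HQ > 1 flags potential non-carcinogenic risk; LTCR is judged against the
# 1e-6 to 1e-4 acceptable band.
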