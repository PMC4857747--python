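"""Uptake stoichiometry: how much milk would a measurable rise require?

Builds two scenarios from reported milk miR-29b concentrations and asks
what it would take to raise an adult's blood concentration by 300 fmol/L.
"""

from xenomir import (
    UptakeScenario,
    pmol_per_l_to_fmol_per_l,
    required_milk_volume,
    required_uptake_fraction,
)

# Scenario 1: skim-milk concentration estimate, perfect uptake.
skim = UptakeScenario(milk_concentration=20.0, target_increase=300.0,
                      blood_volume=5.0, efficiency=1.0)
print(f"at 20 fmol/L milk, 100% uptake: {required_milk_volume(skim):.0f} L of milk needed")

# Scenario 2: the highest reported concentration, a realistic 1 L meal.
rich = UptakeScenario(milk_concentration=pmol_per_l_to_fmol_per_l(150.0),
                      target_increase=300.0, blood_volume=5.0, milk_volume=1.0)
frac, infeasible = required_uptake_fraction(rich)
print(f"at 150 pmol/L milk, 1 L ingested: {frac:.2%} uptake efficiency needed"
      f"{' (infeasible)' if infeasible else ''}")

# 75 L per meal, or >=1% systemic uptake of intact miRNA, are both far
# outside anything measured for dietary small RNA — the mass balance alone
# argues against the uptake hypothesis.
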