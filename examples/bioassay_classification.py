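"""WHO adult-bioassay mortality and resistance classification.

Four replicate tubes of 25 mosquitoes each are exposed at the diagnostic
dose; pooled 24 h mortality classifies the population (>= 98%
susceptible, 90-97% possible resistance, < 90% resistant), and
resistance % = 100 - mortality % is the response the models predict.
"""

from kdrfit import (
    BioassayReplicate,
    BioassayTest,
    DoseClass,
    PopulationKey,
    mortality_percent,
)

test = BioassayTest(
    population=PopulationKey("Delkanda", 2017, "deltamethrin"),
    insecticide="deltamethrin",
    concentration_pct=0.05,
    dose_class=DoseClass.DIAGNOSTIC,
    replicates=(
        BioassayReplicate(25, 22),
        BioassayReplicate(25, 21),
        BioassayReplicate(25, 20),
        BioassayReplicate(25, 21),
    ),
)
result = mortality_percent(test)
print(f"pooled mortality : {result.mortality_pct:.2f} %")
print(f"resistance       : {result.resistance_pct:.2f} %")
print(f"classification   : {result.classification.value}")
# 84/100 dead -> 84% mortality, below the 90% threshold: the population
# is classified resistant at the diagnostic dose.
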