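"""Mutant kdr allele frequencies from the packaged genotype-count table.

Each population's mutant allele frequency at a locus is the allele count
(heterozygotes + twice the mutant homozygotes) over twice the number of
individuals typed at that locus.
"""

from kdrfit import allele_frequency_table, extreme_frequency
from kdrfit.datasets import genotype_count_rows
from kdrfit.genotype_data import round4

records = allele_frequency_table(genotype_count_rows())
print(f"{len(records)} population x locus frequencies\n")
print(f"{'site':<12} {'year':<5} {'phenotype':<23} {'locus':<7} freq")
for rec in records[:6]:
    pop = rec.population
    print(f"{pop.site:<12} {pop.year:<5} {pop.phenotype_label:<23} "
          f"{rec.locus:<7} {round4(rec.mutant_freq):.4f}")
print("...\n")

for locus, symbol in (("F1534C", "C"), ("V1016G", "G")):
    argmax, best = extreme_frequency(records, locus)
    pop = argmax[0].population
    print(f"highest {symbol} allele frequency: {round4(best):.4f} "
          f"({pop.site} {pop.year}, {pop.phenotype_label})")

# The C allele is near fixation in several populations, consistent with
# sustained pyrethroid pressure; G frequencies stay intermediate.
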