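"""In-package study data: genotype counts and narrative bioassay values.

The genotype-count table covers twelve pyrethroid-resistant *Aedes
aegypti* populations (three Sri Lankan study sites x two collection
years x two pyrethroid phenotypes), each typed at the vgsc loci F1534C
and V1016G.  The per-locus sample sizes differ within a population
because not every individual was successfully typed at both loci, so
allele frequencies use per-locus denominators.
"""

from __future__ import annotations

from .genotype_data import LocusGenotypeCounts, PopulationKey

__all__ = ["genotype_count_rows", "REPORTED_MORTALITY"]

# site, year, phenotype, locus, n_typed, n_wild_hom, n_het, n_mut_hom
_TABLE_ROWS = [
    ("Gangodawila", 2017, "Permethrin resistant", "F1534C", 25, 2, 11, 12),
    ("Gangodawila", 2017, "Permethrin resistant", "V1016G", 25, 10, 12, 3),
    ("Gangodawila", 2020, "Permethrin resistant", "F1534C", 29, 2, 10, 17),
    ("Gangodawila", 2020, "Permethrin resistant", "V1016G", 27, 20, 5, 2),
    ("Gangodawila", 2017, "Deltamethrin resistant", "F1534C", 25, 0, 15, 10),
    ("Gangodawila", 2017, "Deltamethrin resistant", "V1016G", 25, 17, 7, 1),
    ("Gangodawila", 2020, "Deltamethrin resistant", "F1534C", 24, 0, 4, 20),
    ("Gangodawila", 2020, "Deltamethrin resistant", "V1016G", 21, 10, 5, 6),
    ("Udahamulla", 2017, "Permethrin resistant", "F1534C", 27, 1, 10, 16),
    ("Udahamulla", 2017, "Permethrin resistant", "V1016G", 27, 9, 17, 1),
    ("Udahamulla", 2020, "Permethrin resistant", "F1534C", 24, 3, 9, 12),
    ("Udahamulla", 2020, "Permethrin resistant", "V1016G", 28, 5, 15, 8),
    ("Udahamulla", 2017, "Deltamethrin resistant", "F1534C", 32, 3, 23, 6),
    ("Udahamulla", 2017, "Deltamethrin resistant", "V1016G", 23, 6, 9, 8),
    ("Udahamulla", 2020, "Deltamethrin resistant", "F1534C", 28, 5, 16, 7),
    ("Udahamulla", 2020, "Deltamethrin resistant", "V1016G", 25, 4, 17, 4),
    ("Delkanda", 2017, "Permethrin resistant", "F1534C", 25, 1, 8, 16),
    ("Delkanda", 2017, "Permethrin resistant", "V1016G", 24, 15, 7, 2),
    ("Delkanda", 2020, "Permethrin resistant", "F1534C", 21, 3, 1, 17),
    ("Delkanda", 2020, "Permethrin resistant", "V1016G", 16, 6, 6, 4),
    ("Delkanda", 2017, "Deltamethrin resistant", "F1534C", 17, 1, 9, 7),
    ("Delkanda", 2017, "Deltamethrin resistant", "V1016G", 11, 3, 8, 0),
    ("Delkanda", 2020, "Deltamethrin resistant", "F1534C", 24, 2, 6, 16),
    ("Delkanda", 2020, "Deltamethrin resistant", "V1016G", 13, 8, 3, 2),
]

#: 24 h mortality percentages reported for named assays
#: (site, year, insecticide, concentration %) -> mortality %
REPORTED_MORTALITY = {
    ("Udahamulla", 2017, "permethrin", 0.75): 54.35,
    ("Delkanda", 2017, "deltamethrin", 0.05): 84.68,
    ("Delkanda", 2017, "malathion", 5.0): 100.0,
    ("Gangodawila", 2017, "malathion", 5.0): 100.0,
    ("Gangodawila", 2020, "permethrin", 0.25): 25.0,
    ("Gangodawila", 2020, "permethrin", 1.25): 49.0,
    ("Gangodawila", 2020, "deltamethrin", 0.03): 45.0,
    ("Gangodawila", 2020, "deltamethrin", 0.15): 100.0,
    ("Delkanda", 2020, "malathion", 0.8): 77.0,
}


def genotype_count_rows() -> list[tuple[PopulationKey, LocusGenotypeCounts]]:
    """The genotype-count table as (population, counts) pairs."""
    return [
        (
            PopulationKey(site, year, phenotype),
            LocusGenotypeCounts(locus, n, wild, het, mut),
        )
        for site, year, phenotype, locus, n, wild, het, mut in _TABLE_ROWS
    ]
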