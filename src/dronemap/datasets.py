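"""Published genome-wide summary statistics for *Apis mellifera* drone mapping.

These numbers come from a published three-colony queen/drone/worker
whole-genome resequencing experiment in the honey bee (43 drones and six
workers informative across three colonies, ~700,000 markers, ~36x
coverage). They serve two purposes here:

* they parameterize the colony simulator's defaults (genome size and
  chromosome proportions, crossover rate, conversion counts, multi-copy
  genome fraction), so that synthetic colonies reproduce the study's
  conditions; and
* they are the *inputs* to the worked-example arithmetic (crossover rate in
  cM/Mb, conversions per meiosis, shared-crossover totals) recomputed by
  the test suite and the acceptance script.

Chromosome lengths are the assembled lengths of the 16 honey-bee
chromosomes in Mb; mean crossover counts are per-chromosome averages over
the 43 drones.
"""

from __future__ import annotations

from types import MappingProxyType

#: assembled chromosome lengths (Mb), Chr1..Chr16; total 219.6 Mb
CHROM_LENGTHS_MB = (
    29.9, 15.5, 13.2, 12.7, 14.4, 18.5, 13.2, 13.5,
    11.1, 13.0, 14.7, 11.9, 10.3, 10.3, 10.2, 7.2,
)

#: mean crossovers per drone per chromosome (43 drones, three colonies)
MEAN_CO_PER_CHROM = (
    13.1, 5.9, 5.9, 5.5, 4.7, 6.9, 4.9, 4.3,
    3.0, 5.7, 4.0, 4.6, 4.1, 3.6, 2.7, 2.6,
)

#: genome-wide study summary used in worked examples
STUDY = MappingProxyType(
    {
        "n_drones": 43,
        "n_workers": 6,
        "genome_mb": 219.6,          # summed assembled chromosome length
        "genome_mb_round": 220.0,    # the rounded figure used genome-wide
        "mean_co_per_gamete": 81.5,
        "total_co": 3505,
        "total_conversions": 250,    # <=10 kb blocks outside multi-copy regions
        "co_associated_conversions": 29,      # within 10 kb of a crossover
        "co_associated_conversions_100kb": 43,  # within 100 kb
        "multicopy_conversions": 45,
        "simple_conversion_fraction": 0.9,  # assumed share of CO-associated
                                            # conversions invisible to haploid typing
        "markers_per_colony": (671690, 740763, 687464),
        # number of crossovers observed in exactly k drones (k >= 1)
        "shared_co_multiplicity": MappingProxyType(
            {1: 2245, 2: 100, 3: 80, 4: 59, 5: 50, 6: 30, 7: 22}
        ),
        "gap_run_length": 50_000,    # length-unknown assembly gaps: run of N
    }
)
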