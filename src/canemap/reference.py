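"""Published genotyping and map counts of the 'IAC66-6' x 'TUC71-7' study.

The raw genotype matrix behind the reference sugarcane map was never
deposited; what its report prints are marker counts and map totals.  Those
counts are inputs here: the package's summary formulas applied to them
reproduce the study's derived statistics (marker density, mean group
length, Bonferroni level, copy numbers, ...), which is how the arithmetic
layer of this package is validated.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ReferenceCounts:
    """Raw printed counts from the reference study (not derived values)."""

    # genotyping
    n_individuals: int = 188
    n_genotyped_loci: int = 992           # markers chi-square tested
    alpha_global: float = 0.05
    n_sdm: int = 730                      # undistorted single-dose markers
    # AFLP
    aflp_scorable_bands: int = 3094
    aflp_combinations: int = 22
    aflp_segregating: int = 685
    aflp_sdm: int = 535
    aflp_linked: int = 395
    # EST-SSR
    ssr_alleles: int = 273
    ssr_loci: int = 41
    ssr_sdm: int = 130
    ssr_linked: int = 95
    # retrotransposon (scIvana_1) markers
    rt_total_fragments: int = 357
    rt_combinations: int = 6
    rt_segregating: int = 87
    rt_sdm: int = 65
    rt_linked: int = 56
    rt_parent1_fragments: int = 316       # fragments present in 'IAC66-6'
    rt_parent2_fragments: int = 324       # fragments present in 'TUC71-7'
    # map
    map_length_cm: float = 4843.19
    n_linked_markers: int = 546
    n_cgs: int = 92


REFERENCE = ReferenceCounts()
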