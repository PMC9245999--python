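"""Forensic parameters straight from a haplotype frequency spectrum.

Reports often print only the spectrum — how many haplotypes were seen
once, twice, three times ... — rather than the raw profiles. HD and DC are
functions of that spectrum alone, so they can be recomputed (and audited)
from the printed counts. The spectrum below is from a 577-male sample:
536 haplotypes seen once, 10 twice, 4 thrice, 1 four and 1 five times.
"""

from ystrpop import discrimination_capacity, haplotype_diversity, round_half_up
from ystrpop.forensic_stats import FrequencySpectrum

spectrum = FrequencySpectrum({1: 536, 2: 10, 3: 4, 4: 1, 5: 1})

print(f"n = {spectrum.n} males, H = {spectrum.n_distinct} distinct haplotypes")
print(f"HD = {round_half_up(haplotype_diversity(spectrum), 4)}")
print(f"DC = {round_half_up(discrimination_capacity(spectrum), 4)}")
print(f"unique: {round_half_up(100 * spectrum.fraction_with_multiplicity(1), 2)}%  "
      f"doubletons: {round_half_up(100 * spectrum.fraction_with_multiplicity(2), 2)}%")
print()
print("Expected output: HD = 0.9998, DC = 0.9567, 97.10% unique, 1.81% twice.")
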