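"""Forensic summary statistics for Y-STR haplotype tables.

Allele and allelic-combination frequencies are obtained by direct counting.
Diversities use Nei's unbiased estimator with the small-sample correction:

    GD = n/(n-1) * (1 - sum_i p_i^2)

applied to per-locus allele (or combination) frequencies, and the same
formula applied to whole-haplotype frequencies gives the haplotype
diversity HD. Discrimination capacity DC is the number of distinct
haplotypes divided by the sample size. Internally the cancellation-free
form n/(n-1) * (1 - sum_j c_j^2 / n^2) over integer counts is used, so an
all-unique sample yields HD == 1.0 exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

from .errors import DegenerateInputError, LookupError_, ValidationError
from .haplotype_io import HaplotypeTable

__all__ = [
    "LocusFrequencyTable",
    "FrequencySpectrum",
    "ForensicSummary",
    "allele_frequencies",
    "gene_diversity",
    "haplotype_spectrum",
    "haplotype_diversity",
    "discrimination_capacity",
    "forensic_summary",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 4) -> float:
    """Round with ties away from zero, matching forensic reporting practice."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class LocusFrequencyTable:
    """Observed allele (or combination) counts and frequencies at one locus."""

    locus: str
    counts: dict[str, int]

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    @property
    def freqs(self) -> dict[str, float]:
        n = self.n
        return {label: c / n for label, c in self.counts.items()}


@dataclass
class FrequencySpectrum:
    """Counts of haplotypes by multiplicity: spectrum[k] = number of
    distinct haplotypes observed exactly k times."""

    spectrum: dict[int, int]

    def __post_init__(self) -> None:
        bad = [k for k, s in self.spectrum.items() if k < 1 or s < 0]
        if bad:
            raise ValidationError(f"invalid spectrum entries at multiplicities {bad}")
        self.spectrum = {k: s for k, s in sorted(self.spectrum.items()) if s > 0}

    @property
    def n(self) -> int:
        return sum(k * s for k, s in self.spectrum.items())

    @property
    def n_distinct(self) -> int:
        return sum(self.spectrum.values())

    def fraction_with_multiplicity(self, k: int) -> float:
        """Share of distinct haplotypes seen exactly k times."""
        return self.spectrum.get(k, 0) / self.n_distinct


@dataclass
class ForensicSummary:
    n: int
    gene_diversities: dict[str, float]
    hd: float
    dc: float
    spectrum: FrequencySpectrum
    allele_count_single_copy: int
    combination_counts: dict[str, int] = field(default_factory=dict)

    @property
    def unique_haplotype_fraction(self) -> float:
        return self.spectrum.fraction_with_multiplicity(1)


def allele_frequencies(table: HaplotypeTable, locus: str) -> LocusFrequencyTable:
    """Tally allele labels (single-copy) or canonical pair labels
    (multi-copy) by direct counting; missing calls are excluded from n."""
    locus_def = table.locus(locus)  # raises LookupError_ on unknown locus
    counts: dict[str, int] = {}
    for row in table.rows:
        call = row.calls[locus]
        if call.missing:
            continue
        label = call.render()
        counts[label] = counts.get(label, 0) + 1
    if not counts:
        raise DegenerateInputError(f"{locus}: all calls missing")
    return LocusFrequencyTable(locus_def.name, counts)


def gene_diversity(freq_table: LocusFrequencyTable | Mapping[str, int]) -> float:
    """Nei's unbiased gene diversity GD = n/(n-1) * (1 - sum p_i^2).

    Accepts a LocusFrequencyTable or a bare label -> count mapping.
    0 iff monomorphic; 1 iff all n observations are distinct.
    """
    counts = freq_table.counts if isinstance(freq_table, LocusFrequencyTable) else dict(freq_table)
    n = sum(counts.values())
    if n < 2:
        raise DegenerateInputError(f"gene diversity undefined for n={n}")
    sum_sq = sum(c * c for c in counts.values())
    return n / (n - 1) * (1.0 - sum_sq / (n * n))


def haplotype_spectrum(
    table: HaplotypeTable, loci_subset: Sequence[str] | None = None
) -> FrequencySpectrum:
    """Multiplicity spectrum of haplotypes compared by exact call equality
    over loci_subset (default: the whole panel).

    Missing calls compare equal only to missing calls.
    """
    if not table.rows:
        raise DegenerateInputError("empty table")
    loci = list(loci_subset) if loci_subset is not None else table.locus_names
    if not loci:
        raise ValidationError("empty locus subset")
    unknown = set(loci) - set(table.locus_names)
    if unknown:
        raise LookupError_(f"loci not in panel: {sorted(unknown)}")
    tallies: dict[tuple, int] = {}
    for row in table.rows:
        key = tuple(row.calls[name] for name in loci)
        tallies[key] = tallies.get(key, 0) + 1
    spectrum: dict[int, int] = {}
    for k in tallies.values():
        spectrum[k] = spectrum.get(k, 0) + 1
    return FrequencySpectrum(spectrum)


def haplotype_diversity(spectrum: FrequencySpectrum) -> float:
    """HD = n/(n-1) * (1 - sum_j q_j^2) over haplotype frequencies q_j.

    Computed from integer counts so the all-unique case is exactly 1.
    """
    n = spectrum.n
    if n < 2:
        raise DegenerateInputError(f"haplotype diversity undefined for n={n}")
    sum_sq = sum(s * k * k for k, s in spectrum.spectrum.items())
    return n / (n - 1) * (1.0 - sum_sq / (n * n))


def discrimination_capacity(spectrum: FrequencySpectrum) -> float:
    """DC = distinct haplotypes / sample size; 1 iff every profile unique."""
    n = spectrum.n
    if n < 1:
        raise DegenerateInputError("empty spectrum")
    return spectrum.n_distinct / n


def forensic_summary(table: HaplotypeTable) -> ForensicSummary:
    """Per-locus GD, HD, DC, allele counts over single-copy loci, and
    combination counts per multi-copy locus for one table."""
    spectrum = haplotype_spectrum(table)
    gds: dict[str, float] = {}
    allele_count = 0
    combination_counts: dict[str, int] = {}
    for locus in table.panel:
        freq = allele_frequencies(table, locus.name)
        gds[locus.name] = gene_diversity(freq)
        if locus.copy_number == 1:
            allele_count += len(freq.counts)
        else:
            combination_counts[locus.name] = len(freq.counts)
    return ForensicSummary(
        n=len(table.rows),
        gene_diversities=gds,
        hd=haplotype_diversity(spectrum),
        dc=discrimination_capacity(spectrum),
        spectrum=spectrum,
        allele_count_single_copy=allele_count,
        combination_counts=combination_counts,
    )
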