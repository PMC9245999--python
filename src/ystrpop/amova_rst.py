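"""Repeat-score distances, AMOVA variance components, and pairwise Rst.

Rst is the microsatellite analogue of Fst: under stepwise mutation the
variance in repeat counts, not haplotype identity, carries the divergence
signal. The estimator here is a single-level analysis of molecular
variance (AMOVA) on squared repeat-score differences. With N samples in
P populations of sizes n_p and d_ij the squared repeat distance between
samples i and j:

    SSD_WP = sum_p (1/n_p) * sum_{i<j in p} d_ij        (within populations)
    SSD_T  = (1/N) * sum_{i<j} d_ij                     (total)
    SSD_AP = SSD_T - SSD_WP                             (among populations)

    sigma2_w = SSD_WP / (N - P)
    sigma2_a = (SSD_AP/(P-1) - sigma2_w) / n_c,   n_c = (N - sum_p n_p^2/N)/(P-1)

    Rst = sigma2_a / (sigma2_a + sigma2_w)

Significance is assessed by permuting individuals between populations
(sizes held fixed) and counting permuted Rst >= observed with the add-one
estimator p = (1 + #{Rst_perm >= Rst_obs}) / (n_perm + 1), so p is never
zero and ties count against significance.

Negative sigma2_a (hence negative Rst) is reported as computed; callers
that need a distance matrix may clamp at zero (see ordination_phylo).
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .errors import DegenerateInputError, ValidationError
from .haplotype_io import Haplotype, HaplotypeTable

__all__ = [
    "AmovaResult",
    "RstMatrix",
    "repeat_scores",
    "repeat_distance",
    "distance_matrix",
    "amova_pair",
    "pairwise_rst",
]

MultiCopyRule = Literal["exclude", "sum"]
MicrovariantRule = Literal["numeric", "exclude"]


@dataclass
class AmovaResult:
    """Variance components and Rst for one population comparison."""

    sigma2_among: float
    sigma2_within: float
    rst: float
    p_value: float | None
    n_permutations: int
    df_among: int
    df_within: int


@dataclass
class RstMatrix:
    """All pairwise Rst values and permutation p-values for a table."""

    labels: list[str]
    rst: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        self.rst = np.asarray(self.rst, dtype=float)
        self.p = np.asarray(self.p, dtype=float)


def repeat_scores(
    hap: Haplotype,
    loci: Sequence[str],
    multi_copy: MultiCopyRule = "exclude",
    microvariant: MicrovariantRule = "numeric",
) -> np.ndarray:
    """Numeric repeat score per locus; NaN where the locus is unusable.

    Single-copy loci score as the numeric designation (microvariant 'R.f'
    counts as R + f/10 under the default rule, or is dropped under
    'exclude'). Multi-copy loci are excluded by default because the two
    designations cannot be assigned to copies; the 'sum' rule scores them
    as the sum of the pair instead.
    """
    out = np.full(len(loci), np.nan)
    for idx, name in enumerate(loci):
        call = hap.calls[name]
        if call.missing:
            continue
        if microvariant == "exclude" and any(a.is_microvariant for a in call.values):
            continue
        if len(call.values) == 1:
            out[idx] = call.values[0].value
        elif multi_copy == "sum":
            out[idx] = sum(a.value for a in call.values)
    return out


def repeat_distance(
    hap_a: Haplotype,
    hap_b: Haplotype,
    loci_subset: Sequence[str] | None = None,
    multi_copy: MultiCopyRule = "exclude",
    microvariant: MicrovariantRule = "numeric",
) -> float:
    """Squared repeat distance d(a, b) = sum_l (r_al - r_bl)^2 over loci
    usable in both haplotypes."""
    loci = list(loci_subset) if loci_subset is not None else list(hap_a.calls)
    ra = repeat_scores(hap_a, loci, multi_copy, microvariant)
    rb = repeat_scores(hap_b, loci, multi_copy, microvariant)
    usable = ~(np.isnan(ra) | np.isnan(rb))
    if not usable.any():
        raise DegenerateInputError("no usable loci shared by the two haplotypes")
    diff = ra[usable] - rb[usable]
    return float(diff @ diff)


def distance_matrix(
    rows: Sequence[Haplotype],
    loci_subset: Sequence[str] | None = None,
    multi_copy: MultiCopyRule = "exclude",
    microvariant: MicrovariantRule = "numeric",
) -> np.ndarray:
    """All pairwise squared repeat distances, pairwise-complete over loci."""
    loci = list(loci_subset) if loci_subset is not None else list(rows[0].calls)
    scores = np.array([repeat_scores(r, loci, multi_copy, microvariant) for r in rows])
    present = ~np.isnan(scores)
    filled = np.where(present, scores, 0.0)
    diff = filled[:, None, :] - filled[None, :, :]
    both = present[:, None, :] & present[None, :, :]
    d = np.sum(np.where(both, diff * diff, 0.0), axis=2)
    if not both.any(axis=2).all():
        raise DegenerateInputError("some haplotype pair shares no usable locus")
    return d


def _amova_from_matrix(d: np.ndarray, groups: Sequence[np.ndarray]) -> tuple[float, float, float]:
    """Variance decomposition (sigma2_a, sigma2_w, Rst) from a squared
    distance matrix and index arrays, one per population."""
    n_tot = sum(len(g) for g in groups)
    n_pop = len(groups)
    ssd_wp = 0.0
    for g in groups:
        sub = d[np.ix_(g, g)]
        ssd_wp += sub.sum() / 2.0 / len(g)
    ssd_t = d.sum() / 2.0 / n_tot
    ssd_ap = ssd_t - ssd_wp
    sigma_w = ssd_wp / (n_tot - n_pop)
    n_c = (n_tot - sum(len(g) ** 2 for g in groups) / n_tot) / (n_pop - 1)
    sigma_a = (ssd_ap / (n_pop - 1) - sigma_w) / n_c
    denom = sigma_a + sigma_w
    rst = sigma_a / denom if denom > 0 else 0.0
    return sigma_a, sigma_w, rst


def _pair_seed(seed: int, label_a: str, label_b: str) -> np.random.SeedSequence:
    """Deterministic substream for one population pair, independent of
    pair ordering and of the order pairs are visited in."""
    key = "\x1f".join(sorted((label_a, label_b))).encode()
    digest = int.from_bytes(hashlib.blake2b(key, digest_size=4).digest(), "big")
    return np.random.SeedSequence([int(seed) & 0x7FFFFFFF, digest & 0x7FFFFFFF])


def amova_pair(
    pop_a_rows: Sequence[Haplotype],
    pop_b_rows: Sequence[Haplotype],
    loci_subset: Sequence[str] | None = None,
    n_perm: int = 999,
    seed: int | np.random.SeedSequence = 0,
    multi_copy: MultiCopyRule = "exclude",
    microvariant: MicrovariantRule = "numeric",
) -> AmovaResult:
    """Two-population AMOVA with a permutation test on Rst.

    Permutations reshuffle individuals between the two populations holding
    sample sizes fixed. n_perm=0 skips the test (p_value None).
    """
    n_a, n_b = len(pop_a_rows), len(pop_b_rows)
    if n_a < 2 or n_b < 2:
        raise DegenerateInputError("each population needs at least 2 samples")
    rows = list(pop_a_rows) + list(pop_b_rows)
    d = distance_matrix(rows, loci_subset, multi_copy, microvariant)
    idx_a = np.arange(n_a)
    idx_b = np.arange(n_a, n_a + n_b)
    sigma_a, sigma_w, rst = _amova_from_matrix(d, [idx_a, idx_b])
    p_value: float | None = None
    if n_perm > 0:
        if isinstance(seed, np.random.SeedSequence):
            rng = np.random.default_rng(seed)
        else:
            rng = np.random.default_rng(np.random.SeedSequence(int(seed) & 0x7FFFFFFF))
        hits = 0
        all_idx = np.arange(n_a + n_b)
        for _ in range(n_perm):
            perm = rng.permutation(all_idx)
            _, _, rst_perm = _amova_from_matrix(d, [perm[:n_a], perm[n_a:]])
            if rst_perm >= rst:
                hits += 1
        p_value = (1 + hits) / (n_perm + 1)
    return AmovaResult(
        sigma2_among=sigma_a,
        sigma2_within=sigma_w,
        rst=rst,
        p_value=p_value,
        n_permutations=n_perm,
        df_among=1,
        df_within=n_a + n_b - 2,
    )


def pairwise_rst(
    table: HaplotypeTable,
    loci_subset: Sequence[str] | None = None,
    n_perm: int = 999,
    seed: int = 0,
    multi_copy: MultiCopyRule = "exclude",
    microvariant: MicrovariantRule = "numeric",
) -> RstMatrix:
    """Pairwise Rst and permutation p-values over every population pair.

    Each pair draws its permutation stream from (seed, sorted label pair),
    so the result does not depend on the order populations appear in the
    table.
    """
    labels = table.population_ids
    if len(labels) < 2:
        raise DegenerateInputError("need at least 2 populations")
    pops = {lab: table.population(lab) for lab in labels}
    for lab, rows in pops.items():
        if len(rows) < 2:
            raise DegenerateInputError(f"population {lab} has fewer than 2 samples")
    k = len(labels)
    rst = np.zeros((k, k))
    p = np.ones((k, k))
    for i, j in itertools.combinations(range(k), 2):
        res = amova_pair(
            pops[labels[i]],
            pops[labels[j]],
            loci_subset,
            n_perm=n_perm,
            seed=_pair_seed(seed, labels[i], labels[j]),
            multi_copy=multi_copy,
            microvariant=microvariant,
        )
        rst[i, j] = rst[j, i] = res.rst
        if res.p_value is not None:
            p[i, j] = p[j, i] = res.p_value
    return RstMatrix(labels=list(labels), rst=rst, p=p)
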