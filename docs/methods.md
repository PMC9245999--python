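# Methods

## Data model

A haplotype table is males × loci. Each locus is defined by a name and a
copy number (1, or 2 for multi-copy loci amplified from duplicated regions,
e.g. DYS385a/b and DYS527a/b). An allele designation is a repeat count plus
an optional one-digit microvariant suffix ("27.2" = 27 full repeats and a
2-base partial repeat); it is stored exactly as an integer pair, never as a
float, because the suffix is nomenclature rather than measurement. For
ordering and distance purposes "R.f" takes the numeric value R + f/10.
Multi-copy calls are unordered pairs canonicalized ascending, which is also
how "allelic combinations" are counted in frequency tables. Missing data is
an empty cell; the bundled panel describes a complete-profile kit, but the
simulator and real-world tables need the convention. A missing call
compares equal only to another missing call in haplotype identity, and
drops the sample from that locus's frequency table.

An optional transform subtracts DYS389I from DYS389II before distance
computation (`adjust_dys389`): the DYS389II amplicon physically contains
DYS389I, so repeat-difference models double-count shared repeats otherwise.
It is off by default because reported designations are conventionally used
as-is.

## Forensic summary statistics

Gene diversity and haplotype diversity use Nei's unbiased estimator
GD = n/(n−1)·(1 − Σ pᵢ²). It is evaluated in the cancellation-free form
n/(n−1)·(1 − Σ cⱼ²/n²) over integer counts, so an all-unique sample gives
HD = 1 exactly rather than 1 − ε. Multi-copy loci are scored over
combination frequencies (the canonical pair labels), consistent with how
combinations are counted. Reported values are rounded half-up to 4 decimal
places (2 for percentages), full precision kept internally. n < 2 raises a
degenerate-input error instead of returning NaN. Discrimination capacity is
DC = H/n over the multiplicity spectrum.

## AMOVA Rst

The repeat distance between two haplotypes is the squared Euclidean
distance over numeric repeat scores, restricted to loci usable in both
profiles. Multi-copy loci are excluded by default — with ambiguous copy
assignment there is no defensible per-copy repeat score — with an opt-in
rule scoring them as the sum of the two designations. Microvariants score
numerically (R + f/10) by default, keeping those samples; an alternative
rule excludes the locus pairwise.

The two-population decomposition follows the standard single-level AMOVA:
SSD_within = Σ_p (1/n_p) Σ_{i<j∈p} d_ij, SSD_total = (1/N) Σ_{i<j} d_ij,
σ²_w = SSD_within/(N−P), σ²_a = (SSD_among/(P−1) − σ²_w)/n_c with
n_c = (N − Σ n_p²/N)/(P−1), and Rst = σ²_a/(σ²_a + σ²_w). Negative σ²_a
(hence negative Rst) is reported as computed — clamping is presentation,
applied only where a true distance is required. The permutation test
shuffles individuals between the pair holding sizes fixed; the p-value uses
the add-one estimator (1 + #{Rst_perm ≥ Rst_obs})/(n_perm + 1) with ≥ as
the (conservative) tie rule, so p ∈ [1/(n_perm+1), 1]. Default 999
permutations. Each population pair derives its random stream from the user
seed and the sorted label pair, making the full matrix independent of
population order and of evaluation order. `n_perm=0` skips the test
(p-value None) for simulation studies that only need point estimates.

## Ordination and trees

MDS is classical (Torgerson) scaling: eigendecomposition of
B = −½·J·D⁽²⁾·J. It is deterministic and exact for Euclidean-embeddable
input, unlike iterative stress-minimizing variants; negative eigenvalues
are reported but never used for axes, and k is reduced with a warning if
fewer positive eigenvalues exist. Explained fractions are taken over the
positive eigenvalues.

PCA of haplogroup-frequency tables mean-centers columns without scaling
(frequencies share a unit) and uses SVD; explained fractions are
eigenvalues over their total and sum to 1.

Neighbor-joining follows the Saitou–Nei Q-criterion, joining the pair
minimizing Q(i,j) = (m−2)d(i,j) − Rᵢ − Rⱼ; ties break at the lowest
(row, column) index pair for determinism. The final three nodes join by the
three-point formulas, yielding an unrooted tree whose path metric equals
any additive input exactly. Negative branch lengths (possible for
non-additive input) are serialized as-is. Negative Rst entries are floored
at zero before MDS/NJ by default (distances must be nonnegative), with a
flag to disable.

## Haplogroup prediction

No standard algorithm exists for STR-based haplogroup assignment, so the
package uses the most transparent one: k-nearest-neighbor majority vote
(default k = 5) under the mean per-locus squared repeat difference,
computed over loci non-missing in both profiles. Multi-copy loci contribute
the cheaper of the two copy pairings and count two locus slots. Vote ties
break by smaller mean distance, then lexicographic label. A query is
"unassigned" when fewer than `locus_overlap_min` (default 10) usable loci
are shared, or the best score exceeds the threshold (default ∞: always
assign when overlap suffices). Raising the threshold can only increase the
assignment rate. Haplogroup labels are opaque flat strings; hierarchical
structure (D1 ⊂ D) is ignored. A Bayesian allele-frequency scorer is a
documented extension point, not implemented.

## Simulator

`synthetic_data` generates tables under the symmetric stepwise mutation
model on a star genealogy: an ancestral haplotype founds each population
t_split time units back; each sampled lineage evolves independently for
t_within units from its founder. Mutation counts per lineage are
Poisson(μ·t); each mutation steps the repeat count ±1 with equal
probability, so a lineage's displacement has variance μ·t and two lineages
separated by total time T satisfy E[(rᵢ−rⱼ)²] = 2μT. This gives the
closed-form test oracles

    d_within  = 2·Σₗ μₗ·t_within
    d_between = 2·Σₗ μₗ·(t_within + t_split)
    E[Rst]   ≈ t_split / (t_split + t_within).

Defaults: μ = 0.05 per locus per time unit, t_within = t_split = 10,
founder allele 15 repeats — mid-range for forensic Y-STRs, deep enough for
polymorphism without saturating the repeat floor. Repeat counts floor at 1
(biological lower bound); the induced bias is negligible at founder alleles
≥ 10 and these depths. Multi-copy loci are two independent single-copy
systems canonicalized into pairs; microvariants can be injected at a
per-designation probability to exercise parsing and distance paths.

What the star genealogy omits: within-population coalescent correlation
(shared internal branches), migration, selection, locus-specific multi-step
mutations. Passing tests therefore demonstrate estimator correctness under
independence, not robustness to genealogical correlation in real samples —
real-data Rst standard errors will exceed the simulated ones.

## Study sizes used in tests

Property tests run at the sizes their statements name: AMOVA oracle checks
on 4+4 and 3+3 instances; null p-value uniformity over 200 replicates of
10+10 samples × 5 loci at 199 permutations (KS test, α = 0.01); Rst
recovery at t_split = t_within over 20 replicates of 50+50 samples × 10
loci; divergence-ordering over 40 replicate 3-point grids; the end-to-end
pipeline at 3 populations × 50 samples × 28 loci with 199 permutations.
These sizes give each check clear statistical power while keeping the suite
fast.

## Known limitations

- Rst on real tables depends on how multi-copy loci and microvariants were
  treated by whatever produced a comparison matrix; the defaults here
  (exclude multi-copy, numeric microvariants) are explicit and switchable,
  and numeric agreement with externally computed matrices is not guaranteed.
- The haplogroup predictor's accuracy bound holds for the stated simulation
  (deep splits, shallow clades); real reference panels with overlapping
  clades will do worse and benefit from finite thresholds.
- Single-level AMOVA only; no hierarchical (region/population) designs, no
  Fst from haplotype identity, no nonmetric MDS, no bootstrap supports.
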