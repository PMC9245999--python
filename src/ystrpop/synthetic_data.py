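"""Forward stepwise-mutation-model (SMM) simulator for Y-STR tables.

The generator emulates the structure the population analyses assume: an
ancestral male founds P populations t_split time units ago; each sampled
lineage then evolves independently for t_within units from its population
founder (a star genealogy). Every locus mutates as a symmetric SMM: the
number of mutations on a lineage of duration t is Poisson(mu * t) and each
mutation shifts the repeat count by +1 or -1 with equal probability, so a
single lineage's displacement has variance mu * t and two lineages with
total separation T satisfy E[(r_i - r_j)^2] = 2 * mu * T.

That yields closed-form expectations used as test oracles:

    d_w  = 2 * sum_l mu_l * t_within              (within-population pairs)
    d_b  = 2 * sum_l mu_l * (t_within + t_split)  (between-population pairs)
    Rst ~= t_split / (t_split + t_within)

Star genealogies omit within-population coalescent correlation, so these
expectations are exact here but only approximate for real populations.
Repeat counts are floored at 1 (bias negligible for founder alleles >= 10).
Multi-copy loci are simulated as two independent single-copy systems and
canonicalized; microvariants can be injected at a per-designation
probability to exercise parsing and distance paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .haplogroup_predict import HaplogroupRefPanel
from .haplotype_io import (
    Allele,
    AlleleCall,
    Haplotype,
    HaplotypeTable,
    LocusDef,
)

__all__ = [
    "PopulationSpec",
    "SimConfig",
    "SimTruth",
    "simulate_table",
    "simulate_reference_panel",
    "default_sim_panel",
]

DEFAULT_FOUNDER_REPEATS = 15


@dataclass(frozen=True)
class PopulationSpec:
    pop_id: str
    n_samples: int
    haplogroup: str = ""


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset.

    mu is the per-locus mutation rate in expected mutations per lineage per
    time unit (one value for all loci or a per-locus mapping); t_within and
    t_split are time depths in the same units. founder_alleles overrides the
    ancestral repeat count per locus (default 15 everywhere).
    """

    panel: list[LocusDef]
    populations: list[PopulationSpec]
    mu: float | Mapping[str, float] = 0.05
    t_within: float = 10.0
    t_split: float = 10.0
    founder_alleles: Mapping[str, int] = field(default_factory=dict)
    microvariant_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.populations = [
            PopulationSpec(*p) if not isinstance(p, PopulationSpec) else p
            for p in self.populations
        ]
        if not self.populations:
            raise ValidationError("at least one population required")
        if any(p.n_samples < 1 for p in self.populations):
            raise ValidationError("sample sizes must be >= 1")
        if self.t_within < 0 or self.t_split < 0:
            raise ValidationError("time depths must be >= 0")
        if any(r < 0 for r in self._mu_vector()):
            raise ValidationError("mutation rates must be >= 0")
        if not 0.0 <= self.microvariant_prob <= 1.0:
            raise ValidationError("microvariant_prob must be in [0, 1]")

    def mu_for(self, locus: str) -> float:
        if isinstance(self.mu, Mapping):
            return float(self.mu[locus])
        return float(self.mu)

    def _mu_vector(self) -> list[float]:
        return [self.mu_for(l.name) for l in self.panel]


@dataclass
class SimTruth:
    """Ground truth retained alongside a simulated table."""

    founders: dict[str, Haplotype]
    expected_within_distance: float
    expected_between_distance: float
    expected_rst: float


def default_sim_panel(n_loci: int, prefix: str = "SIM") -> list[LocusDef]:
    """A plain single-copy panel for simulation studies."""
    return [LocusDef(f"{prefix}{i + 1:02d}", 1) for i in range(n_loci)]


def _smm_steps(rng: np.random.Generator, rate: float, size: int) -> np.ndarray:
    """Net displacement of `size` independent lineages, each accumulating
    Poisson(rate) unit steps of random sign."""
    n_mut = rng.poisson(rate, size=size)
    # sum of n fair +/-1 steps == 2*Binomial(n, 1/2) - n
    return 2 * rng.binomial(n_mut, 0.5) - n_mut


def _amplicons(panel: Sequence[LocusDef]) -> list[tuple[str, int]]:
    """(locus name, copy index) for every independently evolving repeat."""
    out = []
    for locus in panel:
        for copy in range(locus.copy_number):
            out.append((locus.name, copy))
    return out


def _drift(
    rng: np.random.Generator,
    origin: dict[tuple[str, int], int],
    panel: Sequence[LocusDef],
    cfg: SimConfig,
    time: float,
) -> dict[tuple[str, int], int]:
    state = {}
    for key in _amplicons(panel):
        step = int(_smm_steps(rng, cfg.mu_for(key[0]) * time, 1)[0])
        state[key] = max(1, origin[key] + step)
    return state


def _to_haplotype(
    sample_id: str,
    population_id: str,
    state: Mapping[tuple[str, int], int],
    panel: Sequence[LocusDef],
    rng: np.random.Generator,
    microvariant_prob: float,
) -> Haplotype:
    calls = {}
    for locus in panel:
        alleles = []
        for copy in range(locus.copy_number):
            frac = 0
            if microvariant_prob and rng.random() < microvariant_prob:
                frac = int(rng.integers(1, 4))
            alleles.append(Allele(state[(locus.name, copy)], frac))
        calls[locus.name] = AlleleCall(tuple(alleles))
    return Haplotype(sample_id, population_id, calls)


def _expected_distances(cfg: SimConfig) -> tuple[float, float]:
    # expectations over the loci the default distance uses (single-copy)
    mu_sum = sum(cfg.mu_for(l.name) for l in cfg.panel if l.copy_number == 1)
    d_w = 2.0 * mu_sum * cfg.t_within
    d_b = 2.0 * mu_sum * (cfg.t_within + cfg.t_split)
    return d_w, d_b


def simulate_table(config: SimConfig) -> tuple[HaplotypeTable, SimTruth]:
    """Simulate a haplotype table with known population structure.

    Fully reproducible from config.seed: population founders drift from the
    ancestral haplotype for t_split, each sample drifts from its founder
    for t_within.
    """
    rng = np.random.default_rng(config.seed)
    panel = list(config.panel)
    ancestral = {
        key: int(config.founder_alleles.get(key[0], DEFAULT_FOUNDER_REPEATS))
        for key in _amplicons(panel)
    }
    rows: list[Haplotype] = []
    founders: dict[str, Haplotype] = {}
    for pop in config.populations:
        founder_state = _drift(rng, ancestral, panel, config, config.t_split)
        founders[pop.pop_id] = _to_haplotype(
            f"{pop.pop_id}-founder", pop.pop_id, founder_state, panel, rng, 0.0
        )
        for i in range(pop.n_samples):
            state = _drift(rng, founder_state, panel, config, config.t_within)
            rows.append(
                _to_haplotype(
                    f"{pop.pop_id}-{i + 1:04d}",
                    pop.pop_id,
                    state,
                    panel,
                    rng,
                    config.microvariant_prob,
                )
            )
    d_w, d_b = _expected_distances(config)
    t_total = config.t_split + config.t_within
    truth = SimTruth(
        founders=founders,
        expected_within_distance=d_w,
        expected_between_distance=d_b,
        expected_rst=config.t_split / t_total if t_total > 0 else 0.0,
    )
    table = HaplotypeTable(panel, rows, provenance=f"ystrpop simulation seed={config.seed}")
    return table, truth


def simulate_reference_panel(
    config: SimConfig, records_per_haplogroup: int
) -> HaplogroupRefPanel:
    """Simulate a labeled haplogroup reference panel.

    Each population spec's haplogroup label names a founder clade;
    records_per_haplogroup lineages drift t_within from each clade founder.
    """
    labels = [p.haplogroup or p.pop_id for p in config.populations]
    if len(set(labels)) < 2:
        raise ValidationError("need at least 2 distinct haplogroup founders")
    if records_per_haplogroup < 1:
        raise ValidationError("records_per_haplogroup must be >= 1")
    sized = [
        PopulationSpec(lab, records_per_haplogroup, lab) for lab in labels
    ]
    table, _ = simulate_table(
        SimConfig(
            panel=list(config.panel),
            populations=sized,
            mu=config.mu,
            t_within=config.t_within,
            t_split=config.t_split,
            founder_alleles=dict(config.founder_alleles),
            microvariant_prob=config.microvariant_prob,
            seed=config.seed,
        )
    )
    records = [(row.population_id, row) for row in table.rows]
    n_single = sum(l.copy_number for l in config.panel)
    return HaplogroupRefPanel(records, locus_overlap_min=min(10, n_single))
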