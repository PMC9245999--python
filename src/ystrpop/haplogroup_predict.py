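"""Nearest-neighbor Y-haplogroup assignment from STR profiles.

Y haplogroups are clades of the Y-SNP phylogeny; without SNP typing they
can be predicted, imperfectly, from STR repeat profiles because haplotypes
within a clade cluster in repeat space. The predictor is a k-nearest-
neighbor majority vote against a labeled reference panel under a per-locus
normalized squared repeat difference:

    score(q, ref) = (1 / n_loci_used) * sum_l (r_ql - r_refl)^2

over loci non-missing in both profiles. Multi-copy loci contribute through
the minimum-cost pairing of their two designations and count two locus
slots. A query is "unassigned" when it shares fewer than locus_overlap_min
usable loci with the panel or its best score exceeds the threshold.
Haplogroup labels are treated as opaque flat strings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import IO, Sequence

from .errors import DegenerateInputError, ValidationError
from .haplotype_io import Haplotype, HaplotypeTable, LocusDef, read_haplotype_table

__all__ = [
    "HaplogroupRefPanel",
    "HaplogroupCall",
    "profile_score",
    "predict_haplogroup",
    "predict_table",
    "haplogroup_frequencies",
    "read_reference_panel",
]

UNASSIGNED = "unassigned"


@dataclass
class HaplogroupRefPanel:
    """Labeled reference haplotypes used as k-NN exemplars."""

    records: list[tuple[str, Haplotype]]
    locus_overlap_min: int = 10

    def __post_init__(self) -> None:
        for label, hap in self.records:
            if not label:
                raise ValidationError(f"empty haplogroup label for {hap.sample_id}")
            usable = sum(0 if c.missing else len(c.values) for c in hap.calls.values())
            if usable < self.locus_overlap_min:
                raise ValidationError(
                    f"reference {hap.sample_id}: only {usable} usable loci"
                )


@dataclass
class HaplogroupCall:
    sample_id: str
    label: str
    score: float
    n_loci_used: int
    margin: float

    @property
    def assigned(self) -> bool:
        return self.label != UNASSIGNED


def profile_score(query: Haplotype, ref: Haplotype) -> tuple[float, int]:
    """Mean per-locus squared repeat difference and the locus count used.

    Symmetric in its arguments. Multi-copy calls are matched by the cheaper
    of the two possible pairings and count as two loci.
    """
    total = 0.0
    used = 0
    for name, qcall in query.calls.items():
        rcall = ref.calls.get(name)
        if rcall is None or qcall.missing or rcall.missing:
            continue
        if len(qcall.values) != len(rcall.values):
            continue
        if len(qcall.values) == 1:
            diff = qcall.values[0].value - rcall.values[0].value
            total += diff * diff
            used += 1
        else:
            (a1, a2) = (v.value for v in qcall.values)
            (b1, b2) = (v.value for v in rcall.values)
            straight = (a1 - b1) ** 2 + (a2 - b2) ** 2
            crossed = (a1 - b2) ** 2 + (a2 - b1) ** 2
            total += min(straight, crossed)
            used += 2
    if used == 0:
        return math.inf, 0
    return total / used, used


def predict_haplogroup(
    query: Haplotype,
    panel: HaplogroupRefPanel,
    k: int = 5,
    threshold: float = math.inf,
) -> HaplogroupCall:
    """k-NN majority vote; ties broken by smaller mean distance then
    lexicographic label; deterministic."""
    if not panel.records:
        raise ValidationError("empty reference panel")
    scored: list[tuple[float, int, str]] = []
    for label, ref in panel.records:
        score, used = profile_score(query, ref)
        if used >= panel.locus_overlap_min:
            scored.append((score, used, label))
    if not scored:
        return HaplogroupCall(query.sample_id, UNASSIGNED, math.inf, 0, math.inf)
    scored.sort(key=lambda t: (t[0], t[2]))
    neighbors = scored[: min(k, len(scored))]
    by_label: dict[str, list[float]] = {}
    for score, _, label in neighbors:
        by_label.setdefault(label, []).append(score)
    ranking = sorted(
        by_label.items(),
        key=lambda kv: (-len(kv[1]), sum(kv[1]) / len(kv[1]), kv[0]),
    )
    winner = ranking[0][0]
    best_score = min(s for s, _, lab in neighbors if lab == winner)
    n_loci = max(used for s, used, lab in neighbors if lab == winner and s == best_score)
    if len(ranking) > 1:
        margin = min(s for s, _, lab in neighbors if lab != winner) - best_score
    else:
        margin = math.inf
    if best_score > threshold:
        return HaplogroupCall(query.sample_id, UNASSIGNED, best_score, n_loci, margin)
    return HaplogroupCall(query.sample_id, winner, best_score, n_loci, margin)


def predict_table(
    table: HaplotypeTable,
    panel: HaplogroupRefPanel,
    k: int = 5,
    threshold: float = math.inf,
) -> list[HaplogroupCall]:
    return [predict_haplogroup(row, panel, k, threshold) for row in table.rows]


def haplogroup_frequencies(
    calls: Sequence[HaplogroupCall],
) -> tuple[dict[str, float], float]:
    """Label fractions over assigned calls (summing to 1) and the
    assignment rate assigned/total."""
    if not calls:
        raise DegenerateInputError("no calls")
    assigned = [c for c in calls if c.assigned]
    rate = len(assigned) / len(calls)
    counts: dict[str, int] = {}
    for c in assigned:
        counts[c.label] = counts.get(c.label, 0) + 1
    total = len(assigned)
    freqs = {lab: cnt / total for lab, cnt in sorted(counts.items())}
    return freqs, rate


def read_reference_panel(
    stream: IO[str] | str,
    panel: Sequence[LocusDef],
    locus_overlap_min: int = 10,
) -> HaplogroupRefPanel:
    """Reference panel TSV = haplotype-table dialect with the PopulationID
    column carrying the haplogroup label."""
    table = read_haplotype_table(stream, panel)
    records = [(row.population_id, row) for row in table.rows]
    return HaplogroupRefPanel(records, locus_overlap_min)
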