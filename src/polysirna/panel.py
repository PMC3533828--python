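"""Greedy set-cover selection of the first-round siRNA panel.

Covering every candidate gene with as few siRNAs as possible is the set
cover problem over the target sets T_i, NP-hard in general; the classic
greedy rule (pick the siRNA covering the most still-uncovered genes) gives
the H(max|T|) approximation. Ties are broken toward larger total |T| —
re-examining already-covered genes raises the per-gene examination
frequency, which is desirable in a pooled screen — then by higher rule
score, smaller HD-sum, and a lexicographic key for determinism. A final
pruning pass removes picks whose targets ended up fully covered by the
rest of the panel, so every panel member is essential.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .scoring import QualifiedSirna

__all__ = ["Panel", "greedy_select", "panel_stats"]


@dataclass(slots=True)
class Panel:
    """Selected first-round panel R = {r_1 … r_k} and its coverage."""

    selected: list[QualifiedSirna]
    covered: frozenset[str]
    uncovered: frozenset[str]

    @property
    def k(self) -> int:
        return len(self.selected)

    @property
    def avg_exam_freq(self) -> float:
        """Mean number of panel siRNAs examining each covered gene."""
        if not self.covered:
            return 0.0
        return sum(len(s.targets) for s in self.selected) / len(self.covered)


def _tie_key(s: QualifiedSirna) -> tuple:
    # larger |T|, higher rule_score, smaller hd_sum, then lexicographic
    return (-len(s.targets), -s.rule_score, s.hd_sum, s.qualified_seq, s.gene_id, s.offset)


def greedy_select(
    sirnas: Sequence[QualifiedSirna], candidates: Iterable[str]
) -> Panel:
    """Greedy set cover over target sets, with frequency-raising tie-breaks.

    Genes no siRNA targets are reported in ``uncovered``. After the greedy
    loop a pruning pass (reverse selection order, repeated to a fixed
    point) drops any siRNA whose targets are covered by the remaining
    panel, so removing any survivor strictly shrinks the covered set.
    """
    candidate_ids = frozenset(candidates)
    if not sirnas and candidate_ids:
        warnings.warn("no qualified siRNAs: every candidate gene is uncovered")
        return Panel([], frozenset(), candidate_ids)
    coverable = frozenset().union(*(s.targets for s in sirnas)) if sirnas else frozenset()
    uncovered = set(candidate_ids & coverable)
    selected: list[QualifiedSirna] = []
    pool = list(sirnas)
    while uncovered and pool:
        gain = max(len(s.targets & uncovered) for s in pool)
        if gain == 0:
            break
        # re-select among max-gain members with the full tie-break chain
        top = [s for s in pool if len(s.targets & uncovered) == gain]
        best = min(top, key=_tie_key)
        selected.append(best)
        pool.remove(best)
        uncovered -= best.targets

    # prune redundant picks, latest first, until stable
    changed = True
    while changed:
        changed = False
        for i in range(len(selected) - 1, -1, -1):
            rest = frozenset().union(
                *(s.targets for j, s in enumerate(selected) if j != i)
            ) if len(selected) > 1 else frozenset()
            if selected[i].targets <= rest:
                del selected[i]
                changed = True
                break

    covered = (
        frozenset().union(*(s.targets for s in selected)) if selected else frozenset()
    )
    if candidate_ids - coverable:
        warnings.warn(
            f"{len(candidate_ids - coverable)} candidate gene(s) are targeted "
            "by no qualified siRNA and cannot be covered"
        )
    return Panel(selected, covered, candidate_ids - covered)


def panel_stats(
    panel: Panel,
    qualified: Sequence[QualifiedSirna],
    nonredundant: Sequence[QualifiedSirna],
    n_enumerated: int,
    n_after_neighbor_exams: int,
) -> dict:
    """Per-stage design statistics, one field per headline panel metric."""
    n_qual = len(qualified)
    multi = [s for s in qualified if len(s.targets) > 1]
    return {
        "n_enumerated_subsequences": n_enumerated,
        "n_after_far_neighbor_and_powerful_exam": n_after_neighbor_exams,
        "n_qualified_sirnas": n_qual,
        "n_nonredundant_qualified_sirnas": len(nonredundant),
        "avg_targets_per_qualified_sirna": (
            sum(len(s.targets) for s in qualified) / n_qual if n_qual else 0.0
        ),
        "n_multi_target_qualified_sirnas": len(multi),
        "avg_targets_per_multi_target_sirna": (
            sum(len(s.targets) for s in multi) / len(multi) if multi else 0.0
        ),
        "n_selected_first_round": panel.k,
        "n_candidate_genes_examined_first_round": len(panel.covered),
        "avg_examination_frequency": panel.avg_exam_freq,
        "n_uncovered_candidate_genes": len(panel.uncovered),
    }
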