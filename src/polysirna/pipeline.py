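"""End-to-end design pipeline: windows → graph → filters → scoring → panel.

Keeps the per-stage counts (enumerated windows, survivors of the
far_neighbor/powerful exams, qualified, non-redundant, panel size) that
summarise a design run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .core import (
    DesignParams,
    NeighborGraph,
    build_graph,
    enumerate_windows,
    excluded_hit_filter,
    far_neighbor_filter,
    powerful_filter,
)
from .panel import Panel, greedy_select, panel_stats
from .scoring import QualifiedSirna, reduce_redundancy, score_qualified
from .seqio import GeneSetPair

__all__ = ["DesignResult", "run_design", "write_qualified_tsv"]


@dataclass(slots=True)
class DesignResult:
    params: DesignParams
    graph: NeighborGraph
    qualified: list[QualifiedSirna]
    nonredundant: list[QualifiedSirna]
    panel: Panel
    n_enumerated: int
    n_after_neighbor_exams: int

    @property
    def stats(self) -> dict:
        return panel_stats(
            self.panel,
            self.qualified,
            self.nonredundant,
            self.n_enumerated,
            self.n_after_neighbor_exams,
        )


def run_design(
    pair: GeneSetPair,
    params: DesignParams | None = None,
    rules: str = "reynolds",
) -> DesignResult:
    """Run the full qualification and selection pipeline on a gene-set pair."""
    params = params or DesignParams()
    occs = enumerate_windows(pair.candidates, params)
    n_enumerated = len(occs)
    graph = build_graph(occs, params)
    far_neighbor_filter(graph)
    powerful_filter(graph)
    n_after = sum(o.marked for o in graph.occs)
    excluded_hit_filter(graph, pair.excluded, params)
    qualified = score_qualified(graph, rules=rules)
    nonredundant = reduce_redundancy(qualified)
    panel = greedy_select(nonredundant, [c.id for c in pair.candidates])
    return DesignResult(
        params=params,
        graph=graph,
        qualified=qualified,
        nonredundant=nonredundant,
        panel=panel,
        n_enumerated=n_enumerated,
        n_after_neighbor_exams=n_after,
    )


def write_qualified_tsv(
    sirnas: Sequence[QualifiedSirna],
    path: str | Path,
    survivors: frozenset[tuple[str, int]] | None = None,
) -> None:
    """Qualified-siRNA table; survivor column marks the non-redundant set."""
    with open(path, "w") as fh:
        fh.write(
            "gene_id\toffset\tqualified_seq\tguide_seq\ttarget_gene_ids\t"
            "n_targets\trule_score\trule_pass\thd_sum\tmax_neighbor_hd\tsurvivor\n"
        )
        for s in sirnas:
            surv = 1 if survivors is None or s.key in survivors else 0
            fh.write(
                f"{s.gene_id}\t{s.offset}\t{s.qualified_seq}\t{s.guide_seq}\t"
                f"{','.join(sorted(s.targets))}\t{len(s.targets)}\t"
                f"{s.rule_score}\t{int(s.rule_pass)}\t{s.hd_sum}\t"
                f"{s.max_neighbor_hd}\t{surv}\n"
            )
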