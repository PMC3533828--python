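"""Two-round hierarchical group-testing screen plan.

Round 1: each selected multi-target siRNA is one pooled RNAi experiment;
a phenotype in pool i implicates some gene among the siRNA's designed
targets T_i — or among X_i, the genes the duplex's *second* strand might
silence, since either strand of an siRNA duplex can load into RISC. Round
2 retests every gene of every positive pool one-on-one with a
gene-specific siRNA. With k pools and sparse positives this needs far
fewer experiments than the |C| one-on-one baseline.

Strand bookkeeping for X_i: the guide strand (reverse complement of the
qualified sense window) silences the designed targets. If the sense
strand itself loads as guide, it silences transcripts complementary to
it, i.e. transcripts containing windows near revcomp(sense) — the guide's
own letter sequence. X_i therefore collects genes (candidate AND
excluded) holding a window within d_T mismatches of the guide letters.
The literal same-letters reading is available via ``literal=True``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import DesignParams, pack_windows, pack_windows_wild, _MASK01
from .panel import Panel
from .scoring import QualifiedSirna
from .seqio import GeneRecord, GeneSetPair

__all__ = [
    "Pool",
    "Round2Assignment",
    "ScreenPlan",
    "sense_strand_targets",
    "build_round1",
    "decode_and_plan_round2",
    "simulate_screen",
]


@dataclass(slots=True)
class Pool:
    """One first-round pooled experiment: an siRNA, T_i, and X_i."""

    sirna: QualifiedSirna
    targets: frozenset[str]
    sense_targets: frozenset[str]
    outcome: str = "unknown"  # unknown | positive | negative

    @property
    def implicated(self) -> frozenset[str]:
        return self.targets | self.sense_targets


@dataclass(slots=True)
class Round2Assignment:
    """One-on-one retest of a gene implicated by a positive pool."""

    gene_id: str
    sirna: QualifiedSirna | None  # None: no specific qualified siRNA exists
    note: str = ""


@dataclass(slots=True)
class ScreenPlan:
    round1: list[Pool]
    round2: dict[str, list[Round2Assignment]] = field(default_factory=dict)
    baseline_count: int = 0

    @property
    def mean_sense_targets(self) -> float:
        if not self.round1:
            return 0.0
        return sum(len(p.sense_targets) for p in self.round1) / len(self.round1)

    def to_json(self) -> str:
        def pool_obj(p: Pool) -> dict:
            return {
                "gene_id": p.sirna.gene_id,
                "offset": p.sirna.offset,
                "guide_seq": p.sirna.guide_seq,
                "qualified_seq": p.sirna.qualified_seq,
                "targets": sorted(p.targets),
                "sense_targets": sorted(p.sense_targets),
                "outcome": p.outcome,
            }

        obj = {
            "baseline_count": self.baseline_count,
            "round1": [pool_obj(p) for p in self.round1],
            "round2": {
                pool_id: [
                    {
                        "gene_id": a.gene_id,
                        "sirna": None
                        if a.sirna is None
                        else {
                            "gene_id": a.sirna.gene_id,
                            "offset": a.sirna.offset,
                            "guide_seq": a.sirna.guide_seq,
                        },
                        "note": a.note,
                    }
                    for a in assignments
                ]
                for pool_id, assignments in self.round2.items()
            },
        }
        return json.dumps(obj, indent=2)


def _scan_hits(
    probe: str, genes: Iterable[GeneRecord], params: DesignParams
) -> frozenset[str]:
    """Gene ids holding a window within d_T mismatches of probe (N wild)."""
    L, d_t = params.length, params.d_t
    packed_probe = pack_windows([probe])
    hits: set[str] = set()
    for rec in genes:
        if len(rec.seq) < L:
            continue
        windows = [rec.seq[off : off + L] for off in range(len(rec.seq) - L + 1)]
        wpacked, wmask = pack_windows_wild(windows)
        xor = np.bitwise_xor(packed_probe, wpacked)
        folded = np.bitwise_and(np.bitwise_or(xor, xor >> np.uint64(1)), wmask)
        if (np.bitwise_count(folded) <= d_t).any():
            hits.add(rec.id)
    return frozenset(hits)


def sense_strand_targets(
    sirna: QualifiedSirna,
    all_genes: GeneSetPair,
    params: DesignParams,
    literal: bool = False,
) -> frozenset[str]:
    """Possible targets X of the duplex's second strand.

    Scans both candidate and excluded genes for windows within d_T
    mismatches of the second strand's complement (default), or of the
    sense strand letters themselves when ``literal=True``.
    """
    probe = sirna.qualified_seq if literal else sirna.guide_seq
    return _scan_hits(
        probe, list(all_genes.candidates) + list(all_genes.excluded), params
    )


def build_round1(
    panel: Panel,
    all_genes: GeneSetPair,
    params: DesignParams,
    literal: bool = False,
) -> ScreenPlan:
    """One pool per selected siRNA, with T_i and X_i populated."""
    pools = [
        Pool(
            sirna=s,
            targets=s.targets,
            sense_targets=sense_strand_targets(s, all_genes, params, literal),
        )
        for s in panel.selected
    ]
    return ScreenPlan(round1=pools, baseline_count=len(all_genes.candidates))


def _pool_id(pool: Pool) -> str:
    return f"{pool.sirna.gene_id}:{pool.sirna.offset}"


def _specific_sirna(
    gene: str,
    qualified: Sequence[QualifiedSirna],
    all_genes: GeneSetPair,
    params: DesignParams,
    literal: bool,
) -> Round2Assignment:
    """Pick a gene-specific siRNA: targets == {gene}, no outside sense hits."""
    singles = [s for s in qualified if s.targets == frozenset({gene})]
    for s in sorted(singles, key=lambda s: (-s.rule_score, s.hd_sum, s.qualified_seq)):
        if sense_strand_targets(s, all_genes, params, literal) <= {gene}:
            return Round2Assignment(gene, s)
    # fall back: least-off-target siRNA that at least covers the gene
    covering = [s for s in qualified if gene in s.targets]
    if covering:
        best = min(
            covering,
            key=lambda s: (
                len(
                    (s.targets | sense_strand_targets(s, all_genes, params, literal))
                    - {gene}
                ),
                -s.rule_score,
                s.qualified_seq,
            ),
        )
        return Round2Assignment(
            gene, best, note="no specific siRNA; least-off-target alternative"
        )
    return Round2Assignment(
        gene, None, note="no qualified siRNA targets this gene; manual design needed"
    )


def decode_and_plan_round2(
    plan: ScreenPlan,
    outcomes: Mapping[str, str],
    qualified: Sequence[QualifiedSirna],
    all_genes: GeneSetPair,
    params: DesignParams,
    literal: bool = False,
) -> ScreenPlan:
    """Label pools and assign one-on-one round-2 siRNAs for positive pools.

    ``outcomes`` maps pool ids ("gene:offset" of the pool siRNA) to
    "positive"/"negative"; every pool must be labeled. Genes appearing only
    in negative pools are cleared and not retested.
    """
    for pool in plan.round1:
        pid = _pool_id(pool)
        if pid not in outcomes:
            raise ValueError(f"pool {pid} has no outcome label")
        label = outcomes[pid]
        if label not in ("positive", "negative"):
            raise ValueError(f"pool {pid}: invalid outcome {label!r}")
        pool.outcome = label
    plan.round2 = {}
    assigned: dict[str, Round2Assignment] = {}
    for pool in plan.round1:
        if pool.outcome != "positive":
            continue
        entries = []
        for gene in sorted(pool.implicated):
            if gene not in assigned:
                assigned[gene] = _specific_sirna(
                    gene, qualified, all_genes, params, literal
                )
            entries.append(assigned[gene])
        plan.round2[_pool_id(pool)] = entries
    return plan


def simulate_screen(
    plan: ScreenPlan,
    truth: Iterable[str],
    seed: int = 0,
    false_negative_rate: float = 0.0,
) -> dict:
    """Count experiments of the two-round screen against a ground truth.

    A pool reads positive when it implicates at least one truth gene
    (optionally flipped to negative with the given false-negative rate).
    Round 2 retests every gene implicated by a positive pool; noise-free,
    a retested gene is confirmed exactly when it is a truth gene.
    """
    truth_set = frozenset(truth)
    rng = np.random.default_rng(seed)
    positive_pools = []
    for pool in plan.round1:
        pos = bool(pool.implicated & truth_set)
        if pos and false_negative_rate > 0 and rng.random() < false_negative_rate:
            pos = False
        pool.outcome = "positive" if pos else "negative"
        if pos:
            positive_pools.append(pool)
    round2_genes = sorted(
        frozenset().union(*(p.implicated for p in positive_pools))
        if positive_pools
        else frozenset()
    )
    identified = sorted(truth_set & set(round2_genes))
    return {
        "round1_experiments": len(plan.round1),
        "round2_experiments": len(round2_genes),
        "total_experiments": len(plan.round1) + len(round2_genes),
        "baseline_experiments": plan.baseline_count,
        "n_positive_pools": len(positive_pools),
        "identified_genes": identified,
        "n_identified": len(identified),
        "n_truth": len(truth_set),
    }
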