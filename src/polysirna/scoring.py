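"""Design-rule scoring, HD-sum, and redundancy reduction of qualified siRNAs.

Many qualified windows silence exactly the same gene set; only one siRNA
per distinct target set is worth synthesising. Within a target-set group
the survivor is chosen by (1) passing the design rules when any member
does, (2) smallest HD-sum — the sum of Hamming distances to all neighbors,
smaller meaning tighter complementarity to every co-target and plausibly
stronger silencing, (3) smallest maximum neighbor distance, (4) a fixed
lexicographic tie-break for determinism.

The rational-design score follows Reynolds et al. (2004): eight criteria
on the sense 19-mer of the duplex, pass at score ≥ 6. For 21-nt windows
the scoring frame is the first 19 nt of the sense (qualified) sequence.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence
import warnings

from .core import NeighborGraph, WindowOcc, guide_of, target_set

__all__ = [
    "QualifiedSirna",
    "UnsupportedRuleError",
    "reynolds_score",
    "hd_sum",
    "score_qualified",
    "reduce_redundancy",
    "RULE_SETS",
]


class UnsupportedRuleError(ValueError):
    """A rule set that is declared but not implemented was requested."""


@dataclass(frozen=True, slots=True)
class QualifiedSirna:
    """A qualified sense window with its guide siRNA and design metrics."""

    gene_id: str
    offset: int
    qualified_seq: str
    guide_seq: str
    targets: frozenset[str]
    rule_score: int
    rule_pass: bool
    hd_sum: int
    max_neighbor_hd: int

    @property
    def key(self) -> tuple[str, int]:
        return (self.gene_id, self.offset)


def _has_internal_repeat(s: str, min_len: int = 5) -> bool:
    """Self-complementary stretch of >= min_len nt within s.

    Proxy for the Reynolds "internal repeat, Tm < 20 °C" criterion without
    a thermodynamics dependency: a hairpin needs a reverse-complementary
    stretch elsewhere in the strand.
    """
    comp = str.maketrans("ACGT", "TGCA")
    kmers = {s[i : i + min_len] for i in range(len(s) - min_len + 1)}
    return any(k.translate(comp)[::-1] in kmers for k in kmers)


def reynolds_score(sense_19mer: str) -> tuple[int, bool]:
    """Rational siRNA design score of a sense 19-mer; pass at score >= 6.

    Criteria (positions 1-based on the sense strand of the 19-nt duplex;
    A/U read as A/T on DNA): GC content 30–52% (+1); each A/T at positions
    15–19 (+1 each); no internal repeat (+1); A at 19 (+1); A at 3 (+1);
    T at 10 (+1); G or C at 19 (−1); G at 13 (−1).
    """
    s = sense_19mer.upper().replace("U", "T")
    if len(s) != 19:
        raise ValueError(f"Reynolds scoring frame must be 19 nt, got {len(s)}")
    score = 0
    gc = sum(c in "GC" for c in s) / 19
    if 0.30 <= gc <= 0.52:
        score += 1
    score += sum(c in "AT" for c in s[14:19])
    if not _has_internal_repeat(s):
        score += 1
    if s[18] == "A":
        score += 1
    if s[2] == "A":
        score += 1
    if s[9] == "T":
        score += 1
    if s[18] in "GC":
        score -= 1
    if s[12] == "G":
        score -= 1
    return score, score >= 6


def _score_reynolds_frame(qualified_seq: str) -> tuple[int, bool]:
    """Apply Reynolds to the first 19 nt of the sense window.

    Windows shorter than 19 nt cannot be scored; they pass by default with
    a warning so downstream selection still works.
    """
    if len(qualified_seq) < 19:
        warnings.warn(
            "window shorter than 19 nt: design-rule scoring disabled, "
            "all windows treated as passing",
            stacklevel=3,
        )
        return 0, True
    return reynolds_score(qualified_seq[:19])


def _unsupported(name: str) -> Callable[[str], tuple[int, bool]]:
    def _raise(_: str) -> tuple[int, bool]:
        raise UnsupportedRuleError(
            f"rule set {name!r} is declared but not implemented; "
            "available: reynolds"
        )

    return _raise


RULE_SETS: dict[str, Callable[[str], tuple[int, bool]]] = {
    "reynolds": _score_reynolds_frame,
    "hsieh": _unsupported("hsieh"),
    "takasaki": _unsupported("takasaki"),
}


def hd_sum(i: int, graph: NeighborGraph) -> int:
    """Sum of Hamming distances from window i to all of its neighbors."""
    return int(graph.neighbor_dists[i].sum())


def score_qualified(
    graph: NeighborGraph, rules: str = "reynolds"
) -> list[QualifiedSirna]:
    """Turn the surviving marked windows into scored qualified siRNAs."""
    if rules not in RULE_SETS:
        raise UnsupportedRuleError(f"unknown rule set {rules!r}")
    scorer = RULE_SETS[rules]
    out: list[QualifiedSirna] = []
    for i, occ in enumerate(graph.occs):
        if not occ.marked:
            continue
        score, passed = scorer(occ.seq)
        dists = graph.neighbor_dists[i]
        out.append(
            QualifiedSirna(
                gene_id=occ.gene_id,
                offset=occ.offset,
                qualified_seq=occ.seq,
                guide_seq=guide_of(occ.seq),
                targets=target_set(i, graph),
                rule_score=score,
                rule_pass=passed,
                hd_sum=int(dists.sum()),
                max_neighbor_hd=int(dists.max()) if len(dists) else 0,
            )
        )
    return out


def reduce_redundancy(sirnas: Iterable[QualifiedSirna]) -> list[QualifiedSirna]:
    """One siRNA per distinct target set.

    Within a group sharing the same T: restrict to rule-passing members if
    any exist; keep minimal hd_sum; among those drop members with a larger
    max_neighbor_hd than the group minimum; break residual ties by smallest
    qualified_seq then smallest (gene_id, offset). Survivors are returned
    sorted by (gene_id, offset).
    """
    groups: dict[frozenset[str], list[QualifiedSirna]] = defaultdict(list)
    for s in sirnas:
        groups[s.targets].append(s)
    survivors: list[QualifiedSirna] = []
    for members in groups.values():
        passing = [m for m in members if m.rule_pass]
        pool = passing if passing else members
        best_hd = min(m.hd_sum for m in pool)
        pool = [m for m in pool if m.hd_sum == best_hd]
        best_max = min(m.max_neighbor_hd for m in pool)
        pool = [m for m in pool if m.max_neighbor_hd == best_max]
        pool.sort(key=lambda m: (m.qualified_seq, m.gene_id, m.offset))
        survivors.append(pool[0])
    survivors.sort(key=lambda s: (s.gene_id, s.offset))
    return survivors
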