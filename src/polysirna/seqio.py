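"""Sequence I/O and redundancy/overlap pre-filters.

Reads candidate and excluded gene sets from FASTA, normalises them to the
DNA alphabet, and reproduces the identity/coverage-based filters used to
build a non-redundant candidate set and an excluded set free of transcripts
that merely duplicate candidates.

Ratio definitions (computed on the best local alignment between two
sequences):

* ``match_ratio``       — identical aligned bases / alignment span
* ``coverage_ratio``    — alignment span / length of the longer sequence
* ``overlapping_ratio`` — alignment span / length of the shorter sequence

where the alignment span counts matched, mismatched and internally gapped
columns of the local alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from Bio import Align, SeqIO

__all__ = [
    "GeneRecord",
    "GeneSetPair",
    "AlignmentRatios",
    "RemovalRecord",
    "FastaError",
    "read_fasta",
    "write_fasta",
    "pairwise_ratios",
    "dedupe_candidates",
    "remove_overlapping_excluded",
    "write_removal_log",
]

_VALID = set("ACGTN")

Role = Literal["candidate", "excluded"]


class FastaError(ValueError):
    """Malformed FASTA input or invalid record content."""


@dataclass(frozen=True, slots=True)
class GeneRecord:
    """One gene (EST/mRNA) sequence with its role in the design."""

    id: str
    seq: str
    role: Role = "candidate"

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaError("empty record id")
        bad = set(self.seq) - _VALID
        if bad:
            raise FastaError(
                f"record {self.id!r}: invalid characters {sorted(bad)} "
                "(alphabet is A,C,G,T,N after U→T normalisation)"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(slots=True)
class GeneSetPair:
    """Disjoint candidate set C and excluded set E."""

    candidates: list[GeneRecord]
    excluded: list[GeneRecord]

    def __post_init__(self) -> None:
        cids = [r.id for r in self.candidates]
        eids = [r.id for r in self.excluded]
        for name, ids in (("candidate", cids), ("excluded", eids)):
            if len(ids) != len(set(ids)):
                raise FastaError(f"duplicate ids within the {name} set")
        overlap = set(cids) & set(eids)
        if overlap:
            raise FastaError(
                f"candidate and excluded id namespaces overlap: {sorted(overlap)[:5]}"
            )


@dataclass(frozen=True, slots=True)
class AlignmentRatios:
    match_ratio: float
    coverage_ratio: float
    overlapping_ratio: float


@dataclass(frozen=True, slots=True)
class RemovalRecord:
    removed_id: str
    kept_id: str
    match_ratio: float
    coverage_ratio: float
    overlapping_ratio: float
    rule: str


def _normalise(raw: str, rec_id: str) -> str:
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - _VALID
    if bad:
        raise FastaError(
            f"record {rec_id!r}: invalid characters {sorted(bad)}"
        )
    return seq


def read_fasta(path: str | Path, role: Role = "candidate") -> list[GeneRecord]:
    """Read a FASTA file into normalised :class:`GeneRecord` objects.

    Sequences are upper-cased and U is normalised to T; characters outside
    {A,C,G,T,N} raise :class:`FastaError` naming the offending record, as
    does a duplicated record id.
    """
    path = Path(path)
    records: list[GeneRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FastaError(f"{path}: record with empty id")
        if rec.id in seen:
            raise FastaError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(GeneRecord(rec.id, _normalise(str(rec.seq), rec.id), role))
    return records


def write_fasta(records: Iterable[GeneRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# -- pairwise local alignment ratios ---------------------------------------

_ALIGNER = Align.PairwiseAligner(
    mode="local",
    match_score=1,
    mismatch_score=-1,
    open_gap_score=-2,
    extend_gap_score=-2,
)


def pairwise_ratios(a: GeneRecord, b: GeneRecord) -> AlignmentRatios:
    """Match/coverage/overlapping ratios of the best local alignment of a, b.

    The pair is canonicalised by (length, id) before aligning so the result
    is symmetric in its arguments.
    """
    if not a.seq or not b.seq:
        raise ValueError("pairwise_ratios requires non-empty sequences")
    first, second = sorted((a, b), key=lambda r: (len(r.seq), r.id))
    alns = _ALIGNER.align(first.seq, second.seq)
    if len(alns) == 0 or alns.score <= 0:
        return AlignmentRatios(0.0, 0.0, 0.0)
    counts = alns[0].counts()
    span = counts.identities + counts.mismatches + counts.internal_gaps
    if span == 0:
        return AlignmentRatios(0.0, 0.0, 0.0)
    longer = max(len(a.seq), len(b.seq))
    shorter = min(len(a.seq), len(b.seq))
    return AlignmentRatios(
        match_ratio=counts.identities / span,
        coverage_ratio=span / longer,
        overlapping_ratio=span / shorter,
    )


def _shorter_of(a: GeneRecord, b: GeneRecord) -> tuple[GeneRecord, GeneRecord]:
    """(to_remove, to_keep): the shorter record, ties by later id."""
    if len(a.seq) != len(b.seq):
        return (a, b) if len(a.seq) < len(b.seq) else (b, a)
    return (a, b) if a.id > b.id else (b, a)


def dedupe_candidates(
    records: Sequence[GeneRecord],
    match_min: float = 0.95,
    coverage_min: float = 0.85,
) -> tuple[list[GeneRecord], list[RemovalRecord]]:
    """Remove redundant candidates.

    For every pair whose best local alignment has match_ratio > ``match_min``
    AND coverage_ratio > ``coverage_min``, the shorter sequence is removed
    (equal lengths: the lexicographically later id). All pairs of the input
    are examined, so the outcome is independent of input order and the
    operation is idempotent.
    """
    removed: dict[str, RemovalRecord] = {}
    n = len(records)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = records[i], records[j]
            ratios = pairwise_ratios(a, b)
            if ratios.match_ratio > match_min and ratios.coverage_ratio > coverage_min:
                drop, keep = _shorter_of(a, b)
                if drop.id not in removed:
                    removed[drop.id] = RemovalRecord(
                        drop.id,
                        keep.id,
                        ratios.match_ratio,
                        ratios.coverage_ratio,
                        ratios.overlapping_ratio,
                        "redundant_candidate",
                    )
    retained = [r for r in records if r.id not in removed]
    return retained, sorted(removed.values(), key=lambda r: r.removed_id)


def remove_overlapping_excluded(
    pair: GeneSetPair,
    coverage_min: float = 0.85,
    overlap_min: float = 0.90,
) -> tuple[GeneSetPair, list[RemovalRecord]]:
    """Drop excluded records that merely duplicate a candidate.

    An excluded record is dropped when its best local alignment to ANY
    candidate has coverage_ratio > ``coverage_min`` OR overlapping_ratio >
    ``overlap_min``. Candidates are never modified.
    """
    kept: list[GeneRecord] = []
    log: list[RemovalRecord] = []
    for e in pair.excluded:
        hit: RemovalRecord | None = None
        for c in pair.candidates:
            ratios = pairwise_ratios(e, c)
            if ratios.coverage_ratio > coverage_min or ratios.overlapping_ratio > overlap_min:
                hit = RemovalRecord(
                    e.id,
                    c.id,
                    ratios.match_ratio,
                    ratios.coverage_ratio,
                    ratios.overlapping_ratio,
                    "overlaps_candidate",
                )
                break
        if hit is None:
            kept.append(e)
        else:
            log.append(hit)
    return GeneSetPair(list(pair.candidates), kept), log


def write_removal_log(log: Iterable[RemovalRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("removed_id\tkept_id\tmatch_ratio\tcoverage_ratio\toverlapping_ratio\trule\n")
        for r in log:
            fh.write(
                f"{r.removed_id}\t{r.kept_id}\t{r.match_ratio:.4f}\t"
                f"{r.coverage_ratio:.4f}\t{r.overlapping_ratio:.4f}\t{r.rule}\n"
            )
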