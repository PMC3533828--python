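"""Synthetic gene-set generation and brute-force oracles.

The generator emulates the structure that makes multi-target siRNA design
interesting in a real EST library: subfamilies of genes sharing a
near-identical 21-mer (a conserved domain footprint) embedded in unrelated
random background sequence, plus an excluded set that may carry decoy
copies of a planted motif close enough (< d_N) to disqualify the windows
over it. Generation is fully reproducible from the seed and emits a
ground-truth manifest of every planted window.

The oracles re-derive the qualification decision and the neighbor graph
directly from the definitions — per-gene minimum Hamming distances over
all windows, plain byte comparison — independently of the packed-popcount
pipeline they are used to check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import DesignParams, WindowOcc, enumerate_windows
from .seqio import GeneRecord, GeneSetPair

__all__ = [
    "FixtureSpec",
    "PlantedWindow",
    "generate",
    "oracle_qualified",
    "oracle_graph",
    "write_truth_tsv",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True, slots=True)
class PlantedWindow:
    gene_id: str
    offset: int
    family: int
    mismatches: int
    decoy: bool = False


@dataclass(slots=True)
class FixtureSpec:
    """Parameters of one synthetic candidate/excluded gene-set instance.

    Defaults are the desk-scale study conditions used throughout the test
    suite: 15 candidate + 15 excluded genes of 350 nt (≈4,950 candidate
    windows), four 3-member subfamilies sharing a planted 21-mer with 2
    mismatches between members (within d_T=4, creating multi-target
    siRNAs), and one family with a decoy copy in the excluded set at
    distance d_N−1 = 4 (an excluded-gene hit).
    """

    n_candidates: int = 15
    n_excluded: int = 15
    gene_len: int = 350
    n_families: int = 4
    family_size: int = 3
    planted_mismatches: int = 2
    decoy_families: int = 1
    decoy_mismatches: int = 4
    n_rate: float = 0.0
    seed: int = 0
    params: DesignParams = field(default_factory=DesignParams)

    def validate(self) -> None:
        L = self.params.length
        if self.gene_len < L:
            raise ValueError("gene_len must be at least the window length")
        if not 0 <= self.planted_mismatches < L:
            raise ValueError("planted_mismatches must lie in [0, L)")
        if not 0 <= self.decoy_mismatches < L:
            raise ValueError("decoy_mismatches must lie in [0, L)")
        if self.n_families * self.family_size > self.n_candidates:
            raise ValueError("families need more candidate genes than available")
        if self.decoy_families > self.n_families:
            raise ValueError("decoy_families exceeds n_families")
        if not 0 <= self.n_rate < 1:
            raise ValueError("n_rate must lie in [0, 1)")


def _mutate(motif: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Copy of motif with exactly k substitutions to different bases."""
    out = motif.copy()
    if k == 0:
        return out
    pos = rng.choice(len(motif), size=k, replace=False)
    for p in pos:
        choices = _BASES[_BASES != out[p]]
        out[p] = rng.choice(choices)
    return out


def generate(spec: FixtureSpec) -> tuple[GeneSetPair, list[PlantedWindow]]:
    """Build a gene-set pair with planted family motifs and a truth manifest.

    Background bases are i.i.d. uniform over {A,C,G,T}; each family's motif
    is written into `family_size` distinct candidate genes at a random
    offset with exactly `planted_mismatches` substitutions per member (the
    first member carries the exact motif). The first `decoy_families`
    motifs are also copied into one excluded gene each at
    `decoy_mismatches` substitutions. N masking (rate `n_rate`) is applied
    to background positions only, never inside planted windows.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    L = spec.params.length
    glen = spec.gene_len

    cand_seqs = rng.choice(_BASES, size=(spec.n_candidates, glen))
    excl_seqs = rng.choice(_BASES, size=(spec.n_excluded, glen))
    protected_c = np.zeros((spec.n_candidates, glen), dtype=bool)
    protected_e = np.zeros((spec.n_excluded, glen), dtype=bool)
    truth: list[PlantedWindow] = []

    members = rng.permutation(spec.n_candidates)[: spec.n_families * spec.family_size]
    members = members.reshape(spec.n_families, spec.family_size)
    for fam in range(spec.n_families):
        motif = rng.choice(_BASES, size=L)
        for rank, gi in enumerate(members[fam]):
            k = 0 if rank == 0 else spec.planted_mismatches
            window = _mutate(motif, k, rng)
            off = int(rng.integers(0, glen - L + 1))
            cand_seqs[gi, off : off + L] = window
            protected_c[gi, off : off + L] = True
            truth.append(PlantedWindow(f"C{gi:03d}", off, fam, k))
        if fam < spec.decoy_families and spec.n_excluded:
            ei = int(rng.integers(0, spec.n_excluded))
            window = _mutate(motif, spec.decoy_mismatches, rng)
            off = int(rng.integers(0, glen - L + 1))
            excl_seqs[ei, off : off + L] = window
            protected_e[ei, off : off + L] = True
            truth.append(
                PlantedWindow(f"E{ei:03d}", off, fam, spec.decoy_mismatches, decoy=True)
            )

    if spec.n_rate > 0:
        for seqs, protected in ((cand_seqs, protected_c), (excl_seqs, protected_e)):
            mask = (rng.random(seqs.shape) < spec.n_rate) & ~protected
            seqs[mask] = ord("N")

    candidates = [
        GeneRecord(f"C{i:03d}", cand_seqs[i].tobytes().decode(), "candidate")
        for i in range(spec.n_candidates)
    ]
    excluded = [
        GeneRecord(f"E{i:03d}", excl_seqs[i].tobytes().decode(), "excluded")
        for i in range(spec.n_excluded)
    ]
    return GeneSetPair(candidates, excluded), truth


def write_truth_tsv(truth: Sequence[PlantedWindow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\toffset\tfamily\tmismatches\tdecoy\n")
        for t in truth:
            fh.write(f"{t.gene_id}\t{t.offset}\t{t.family}\t{t.mismatches}\t{int(t.decoy)}\n")


# -- brute-force oracles ----------------------------------------------------


class InstanceTooLarge(ValueError):
    """Oracle refused: instance exceeds the brute-force size bound."""


def _byte_windows(seq: str, L: int, skip_n: bool) -> list[str]:
    wins = [seq[i : i + L] for i in range(len(seq) - L + 1)]
    if skip_n:
        wins = [w for w in wins if "N" not in w]
    return wins


def _min_hd_per_window(
    probes: np.ndarray, gene_windows: list[str], wildcard_n: bool
) -> np.ndarray:
    """Min Hamming distance of each probe row to any window of one gene.

    ``probes`` is (n, L) uint8. N in gene windows matches any base when
    ``wildcard_n``.
    """
    L = probes.shape[1]
    if not gene_windows:
        return np.full(probes.shape[0], L + 1, dtype=np.int64)
    gw = np.frombuffer("".join(gene_windows).encode(), dtype=np.uint8).reshape(
        len(gene_windows), L
    )
    diff = probes[:, None, :] != gw[None, :, :]
    if wildcard_n:
        diff &= gw[None, :, :] != ord("N")
    return diff.sum(axis=2).min(axis=1)


def oracle_qualified(
    pair: GeneSetPair,
    params: DesignParams,
    max_windows: int = 6000,
) -> dict[tuple[str, int], frozenset[str]]:
    """Direct evaluation of the qualified-sequence definition.

    For every N-free candidate window r: T(r) = genes with some window
    within d_T of r; r is qualified iff every other gene — candidate or
    excluded — has all windows at distance >= d_N from r. Candidate genes
    contribute only N-free windows (an N-masked region is invisible to the
    design); excluded windows are scanned with N matching any base.
    Returns {(gene_id, offset): T} for every qualified window. No graph
    filters are involved.
    """
    L, d_t, d_n = params.length, params.d_t, params.d_n
    occs = enumerate_windows(pair.candidates, params)
    if len(occs) > max_windows:
        raise InstanceTooLarge(
            f"{len(occs)} candidate windows exceeds the oracle bound of "
            f"{max_windows}; use a smaller instance"
        )
    if not occs:
        return {}
    probes = np.frombuffer(
        "".join(o.seq for o in occs).encode(), dtype=np.uint8
    ).reshape(len(occs), L)

    n = len(occs)
    target_sets: list[set[str]] = [set() for _ in range(n)]
    disqualified = np.zeros(n, dtype=bool)
    for rec in pair.candidates:
        mins = _min_hd_per_window(probes, _byte_windows(rec.seq, L, True), False)
        in_t = mins <= d_t
        for i in np.flatnonzero(in_t):
            target_sets[i].add(rec.id)
        disqualified |= ~in_t & (mins < d_n)
    for rec in pair.excluded:
        mins = _min_hd_per_window(probes, _byte_windows(rec.seq, L, False), True)
        disqualified |= mins < d_n
    return {
        (o.gene_id, o.offset): frozenset(target_sets[i])
        for i, o in enumerate(occs)
        if not disqualified[i]
    }


def oracle_graph(
    occs: Sequence[WindowOcc], params: DesignParams
) -> tuple[list[set[int]], list[set[int]]]:
    """All-pairs neighbor / far_neighbor relations by plain byte comparison."""
    n = len(occs)
    nbrs: list[set[int]] = [set() for _ in range(n)]
    fars: list[set[int]] = [set() for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            hd = sum(a != b for a, b in zip(occs[i].seq, occs[j].seq))
            if hd <= params.d_t:
                nbrs[i].add(j)
                nbrs[j].add(i)
            elif hd < params.d_n:
                fars[i].add(j)
                fars[j].add(i)
    return nbrs, fars
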