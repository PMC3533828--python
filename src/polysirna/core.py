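"""Window enumeration, Hamming neighbor graph, and the qualification filters.

The design problem: choose length-L windows of the candidate genes whose
reverse complements (guide siRNAs) silence a well-defined target set T —
every gene of T holds a window within d_T mismatches — while every window
of every other gene (candidate or excluded) is at least d_N mismatches
away. Windows at Hamming distance ≤ d_T are *neighbors* (co-silenced);
windows strictly between d_T and d_N are *far_neighbors* (silencing
uncertain, so disqualifying unless they fall inside the target set anyway).

Filters run in order — far_neighbor exam, powerful-subsequence dominance,
excluded-gene hit exam — as single passes over a mark vector; the neighbor
graph is built once over all enumerated windows and never rebuilt.

Distances are computed exactly on 2-bit-packed windows (one ``uint64`` per
window for L ≤ 32) with vectorised XOR + popcount; every relation equals
the naive all-pairs byte comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .seqio import GeneRecord

__all__ = [
    "DesignParams",
    "WindowOcc",
    "NeighborGraph",
    "enumerate_windows",
    "hamming",
    "build_graph",
    "target_set",
    "far_neighbor_filter",
    "powerful_filter",
    "excluded_hit_filter",
    "guide_of",
    "revcomp",
]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMP = str.maketrans("ACGTN", "TGCAN")

# 0b01 repeated at every even bit position: one indicator bit per base.
_MASK01 = np.uint64(0x5555555555555555)


@dataclass(frozen=True, slots=True)
class DesignParams:
    """Window length and mismatch thresholds of the design.

    ``d_t`` — most mismatches tolerated between a guide and a silenced
    target window; ``d_n`` — fewest mismatches required to every window of
    every non-target gene. Must satisfy L > d_n > d_t ≥ 0.
    """

    length: int = 21
    d_t: int = 4
    d_n: int = 5

    def __post_init__(self) -> None:
        if not (self.length > self.d_n > self.d_t >= 0):
            raise ValueError(
                f"require L > d_N > d_T >= 0, got L={self.length}, "
                f"d_N={self.d_n}, d_T={self.d_t}"
            )
        if self.length > 32:
            raise ValueError("window length above 32 nt is not supported")


@dataclass(slots=True)
class WindowOcc:
    """One length-L window occurrence, keyed by (gene_id, offset)."""

    gene_id: str
    offset: int  # 0-based; window covers [offset, offset + L)
    seq: str
    marked: bool = True
    powerful: bool = False


@dataclass(slots=True)
class NeighborGraph:
    """Neighbor / far_neighbor relations over window occurrences.

    ``neighbors[i]`` and ``far_neighbors[i]`` hold indices into ``occs``;
    ``neighbor_dists[i]`` the matching Hamming distances. Both relations
    are symmetric and irreflexive and never overlap.
    """

    occs: list[WindowOcc]
    params: DesignParams
    neighbors: list[np.ndarray]
    far_neighbors: list[np.ndarray]
    neighbor_dists: list[np.ndarray]

    def __len__(self) -> int:
        return len(self.occs)


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def guide_of(qualified_seq: str) -> str:
    """Guide (antisense) siRNA of a qualified sense window, 5'→3' DNA."""
    return revcomp(qualified_seq)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError(f"unequal lengths {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def enumerate_windows(
    candidates: Iterable[GeneRecord], params: DesignParams
) -> list[WindowOcc]:
    """All N-free length-L windows of the candidate genes, initially marked.

    Order is (gene order, offset). Genes shorter than L yield no windows.
    Duplicate window sequences at different loci stay distinct occurrences.
    """
    L = params.length
    occs: list[WindowOcc] = []
    for rec in candidates:
        seq = rec.seq
        # rightmost N at or left of each position, for O(1) N-free checks
        last_n = -1
        n_positions = [i for i, c in enumerate(seq) if c == "N"]
        n_idx = 0
        for off in range(len(seq) - L + 1):
            while n_idx < len(n_positions) and n_positions[n_idx] < off:
                n_idx += 1
            if n_idx < len(n_positions) and n_positions[n_idx] < off + L:
                continue
            occs.append(WindowOcc(rec.id, off, seq[off : off + L]))
    return occs


# -- packed distance machinery ---------------------------------------------


def pack_windows(seqs: Sequence[str]) -> np.ndarray:
    """2-bit-pack windows (A=0, C=1, G=2, T=3) into one uint64 each."""
    if not seqs:
        return np.zeros(0, dtype=np.uint64)
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), -1)
    codes = np.zeros_like(arr)
    for base, code in _CODE.items():
        codes[arr == ord(base)] = code
    L = arr.shape[1]
    shifts = (2 * np.arange(L, dtype=np.uint64))[None, :]
    return (codes.astype(np.uint64) << shifts).sum(axis=1, dtype=np.uint64)


def pack_windows_wild(seqs: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Pack windows that may contain N; returns (codes, per-window mask).

    The mask carries a 01 indicator at every non-N position, so a masked
    popcount counts mismatches only where the window base is determined
    (N matches any base, contributing distance 0).
    """
    if not seqs:
        return np.zeros(0, dtype=np.uint64), np.zeros(0, dtype=np.uint64)
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), -1)
    codes = np.zeros_like(arr)
    for base, code in _CODE.items():
        codes[arr == ord(base)] = code
    is_n = arr == ord("N")
    codes[is_n] = 0
    L = arr.shape[1]
    shifts = (2 * np.arange(L, dtype=np.uint64))[None, :]
    packed = (codes.astype(np.uint64) << shifts).sum(axis=1, dtype=np.uint64)
    mask = ((~is_n).astype(np.uint64) << shifts).sum(axis=1, dtype=np.uint64)
    return packed, mask


def packed_hd(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Elementwise Hamming distance between broadcastable packed arrays."""
    xor = np.bitwise_xor(x, y)
    folded = np.bitwise_and(np.bitwise_or(xor, xor >> np.uint64(1)), _MASK01)
    return np.bitwise_count(folded).astype(np.uint8)


def build_graph(
    occs: Sequence[WindowOcc], params: DesignParams, chunk: int = 512
) -> NeighborGraph:
    """Exact neighbor/far_neighbor relations over all window occurrences."""
    n = len(occs)
    neighbors: list[np.ndarray] = [np.zeros(0, dtype=np.int64) for _ in range(n)]
    fars: list[np.ndarray] = [np.zeros(0, dtype=np.int64) for _ in range(n)]
    ndists: list[np.ndarray] = [np.zeros(0, dtype=np.uint8) for _ in range(n)]
    if n:
        packed = pack_windows([o.seq for o in occs])
        d_t, d_n = params.d_t, params.d_n
        idx = np.arange(n)
        for start in range(0, n, chunk):
            stop = min(start + chunk, n)
            hd = packed_hd(packed[start:stop, None], packed[None, :])
            for i in range(start, stop):
                row = hd[i - start]
                nb = idx[(row <= d_t) & (idx != i)]
                neighbors[i] = nb
                ndists[i] = row[nb]
                fars[i] = idx[(row > d_t) & (row < d_n)]
    return NeighborGraph(list(occs), params, neighbors, fars, ndists)


def target_set(i: int, graph: NeighborGraph) -> frozenset[str]:
    """Target gene set T of window i: its own gene plus its neighbors'."""
    genes = {graph.occs[i].gene_id}
    genes.update(graph.occs[j].gene_id for j in graph.neighbors[i])
    return frozenset(genes)


def far_neighbor_filter(graph: NeighborGraph) -> None:
    """Unmark windows with a far_neighbor outside their own target set.

    A far_neighbor is not guaranteed to be silenced, so it is tolerable
    only if its gene is already a target via some true neighbor. Single
    pass; marks set by this pass do not feed back into it.
    """
    for i, occ in enumerate(graph.occs):
        if not occ.marked:
            continue
        fars = graph.far_neighbors[i]
        if len(fars) == 0:
            continue
        T = target_set(i, graph)
        if any(graph.occs[j].gene_id not in T for j in fars):
            occ.marked = False


def powerful_filter(graph: NeighborGraph) -> None:
    """Flag powerful windows and unmark the windows they dominate.

    A window P is *powerful* when the neighbors of its neighbors introduce
    nothing new: ∪_{v∈N(P)} N(v) ⊆ N(P) ∪ {P}. Every target reachable from
    a dominated neighbor is then reachable from P itself, so non-powerful
    neighbors of a still-marked powerful window are unmarked without losing
    any coverable gene. Single pass over the pre-pass mark state.
    """
    n = len(graph.occs)
    nbr_sets = [set(graph.neighbors[i].tolist()) for i in range(n)]
    for i, occ in enumerate(graph.occs):
        closed = nbr_sets[i] | {i}
        occ.powerful = all(nbr_sets[v] <= closed for v in nbr_sets[i])
    marked_before = [o.marked for o in graph.occs]
    for i, occ in enumerate(graph.occs):
        if not marked_before[i] or occ.powerful:
            continue
        if any(graph.occs[v].powerful and marked_before[v] for v in nbr_sets[i]):
            occ.marked = False


def excluded_hit_filter(
    graph: NeighborGraph,
    excluded: Iterable[GeneRecord],
    params: DesignParams | None = None,
    chunk: int = 2048,
) -> None:
    """Unmark windows within < d_N mismatches of any excluded-gene window.

    Excluded-gene windows containing N are scanned with N matching any base
    (conservative: an undetermined base may hide a match).
    """
    params = params or graph.params
    L, d_n = params.length, params.d_n
    marked_idx = [i for i, o in enumerate(graph.occs) if o.marked]
    if not marked_idx:
        return
    ex_windows = [
        rec.seq[off : off + L]
        for rec in excluded
        for off in range(len(rec.seq) - L + 1)
    ]
    if not ex_windows:
        return
    packed = pack_windows([graph.occs[i].seq for i in marked_idx])
    ex_packed, ex_mask = pack_windows_wild(ex_windows)
    hit = np.zeros(len(marked_idx), dtype=bool)
    for start in range(0, len(ex_windows), chunk):
        stop = min(start + chunk, len(ex_windows))
        xor = np.bitwise_xor(packed[:, None], ex_packed[None, start:stop])
        folded = np.bitwise_and(
            np.bitwise_or(xor, xor >> np.uint64(1)),
            np.bitwise_and(ex_mask[None, start:stop], _MASK01),
        )
        hd = np.bitwise_count(folded)
        hit |= (hd < d_n).any(axis=1)
    for flag, i in zip(hit, marked_idx):
        if flag:
            graph.occs[i].marked = False
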