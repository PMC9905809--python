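"""Peptide-specificity summaries and TCR-surface phylogenetics.

A position-specific scoring matrix and Shannon information content
summarize the specificity of a groove from a user-supplied list of binder
peptides (the logo transform; no affinity prediction happens here).  On the
TCR side, p-distances over the TCR-contact (TB) positions of an allele
panel feed a neighbor-joining tree, used to pick base alleles with maximally
dissimilar TCR surfaces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .design import AlleleSequence

__all__ = [
    "AA_ORDER",
    "PSSM",
    "LogoMatrix",
    "TcrSurfaceMatrix",
    "build_pssm",
    "information_content",
    "tcr_surface_distance",
    "nj_tree",
]

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"  # row order of every 20-column table
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}


@dataclass
class PSSM:
    """Per-position residue frequencies with additive pseudocount."""

    length: int
    freq: np.ndarray  # (length, 20), rows sum to 1
    pseudocount: float
    n_sequences: int


@dataclass
class LogoMatrix:
    """Shannon-logo letter heights: frequency scaled by information content."""

    heights: np.ndarray  # (length, 20), bits
    ic: np.ndarray  # (length,), bits in [0, log2(20)]


@dataclass
class TcrSurfaceMatrix:
    taxa: list[str]
    D: np.ndarray  # symmetric p-distance matrix, zero diagonal


def build_pssm(peptides: Sequence[str], pseudocount: float = 0.05) -> PSSM:
    """Position frequency matrix: ``(count + a) / (n + 20a)`` per residue."""
    if not peptides:
        raise ValueError("need at least one peptide")
    length = len(peptides[0])
    counts = np.zeros((length, 20))
    for pep in peptides:
        if len(pep) != length:
            raise ValueError(
                f"ragged peptide lengths: {len(pep)} vs {length} ({pep!r})"
            )
        for p, aa in enumerate(pep.upper()):
            try:
                counts[p, _AA_INDEX[aa]] += 1
            except KeyError:
                raise ValueError(f"non-canonical residue {aa!r} in {pep!r}") from None
    n = len(peptides)
    freq = (counts + pseudocount) / (n + 20 * pseudocount)
    return PSSM(length=length, freq=freq, pseudocount=pseudocount, n_sequences=n)


def information_content(pssm: PSSM) -> LogoMatrix:
    """IC per position: ``log2(20) + sum_a f log2 f`` (0 for uniform rows,
    log2(20) ~ 4.32 bits for a single-residue row); heights = freq * IC."""
    f = pssm.freq
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(f > 0, f * np.log2(f), 0.0)
    ic = np.log2(20.0) + plogp.sum(axis=1)
    ic = np.clip(ic, 0.0, np.log2(20.0))
    return LogoMatrix(heights=f * ic[:, None], ic=ic)


def tcr_surface_distance(
    alleles: Sequence[AlleleSequence], tb_positions: Iterable[int]
) -> TcrSurfaceMatrix:
    """Pairwise p-distance over the TCR-contact positions (1-based)."""
    positions = sorted(set(tb_positions))
    if not positions:
        raise ValueError("no TB positions given")
    rows = []
    for allele in alleles:
        if positions[-1] > len(allele):
            raise ValueError(
                f"{allele.name} (length {len(allele)}) does not cover "
                f"TB position {positions[-1]}"
            )
        rows.append([allele.residue(p) for p in positions])
    n = len(alleles)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diff = sum(1 for a, b in zip(rows[i], rows[j]) if a != b)
            D[i, j] = D[j, i] = diff / len(positions)
    return TcrSurfaceMatrix(taxa=[a.name for a in alleles], D=D)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = ("label", "children")  # children: list of (node, branch_length)

    def __init__(self, label: str | None = None) -> None:
        self.label = label
        self.children: list[tuple["_Node", float]] = []

    def newick(self) -> str:
        if not self.children:
            return _quote(self.label or "")
        inner = ",".join(f"{child.newick()}:{bl:.10g}" for child, bl in self.children)
        return f"({inner})"


def _quote(label: str) -> str:
    if any(ch in label for ch in " ,():;'\t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _clamp(li: float, lj: float) -> tuple[float, float]:
    # negative branch lengths: clamp to 0, move the deficit to the sister
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def nj_tree(matrix: TcrSurfaceMatrix, allow_two: bool = False) -> str:
    """Neighbor joining (Saitou-Nei) on a distance matrix, as newick.

    Joins minimize the Q criterion, ties broken by the lowest taxon-index
    pair; the unrooted tree is serialized with a trifurcating root.  On an
    additive matrix the reconstructed path lengths equal the input distances
    exactly.
    """
    D = np.array(matrix.D, dtype=float)
    n = len(matrix.taxa)
    if D.shape != (n, n):
        raise ValueError("distance matrix shape does not match taxa")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0.0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if n == 2 and allow_two:
        a, b = (_quote(t) for t in matrix.taxa)
        return f"({a}:{D[0, 1] / 2:.10g},{b}:{D[0, 1] / 2:.10g});"
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")

    nodes: list[_Node] = [_Node(t) for t in matrix.taxa]
    active = list(range(n))
    dist = {(i, j): D[i, j] for i in range(n) for j in range(n)}
    next_id = n

    def d(i: int, j: int) -> float:
        return dist[(i, j)] if i <= j else dist[(j, i)]

    node_of = {i: nodes[i] for i in range(n)}

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d(i, k) for k in active if k != i) for i in active}
        best: tuple[float, int, int] | None = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d(i, j) - r[i] - r[j]
                key = (q, i, j)
                if best is None or key < best:
                    best = key
        _, i, j = best  # type: ignore[misc]
        dij = d(i, j)
        li = dij / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        li, lj = _clamp(li, lj)
        new = _Node()
        new.children = [(node_of[i], li), (node_of[j], lj)]
        u = next_id
        next_id += 1
        for k in active:
            if k in (i, j):
                continue
            dist[(min(k, u), max(k, u))] = (d(i, k) + d(j, k) - dij) / 2
        dist[(u, u)] = 0.0
        node_of[u] = new
        active = [k for k in active if k not in (i, j)] + [u]

    # three remaining nodes: the three-point formulas
    a, b, c = active
    la = (d(a, b) + d(a, c) - d(b, c)) / 2
    lb = (d(a, b) + d(b, c) - d(a, c)) / 2
    lc = (d(a, c) + d(b, c) - d(a, b)) / 2
    root = _Node()
    root.children = [
        (node_of[a], max(la, 0.0)),
        (node_of[b], max(lb, 0.0)),
        (node_of[c], max(lc, 0.0)),
    ]
    inner = ",".join(f"{child.newick()}:{bl:.10g}" for child, bl in root.children)
    return f"({inner});"
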