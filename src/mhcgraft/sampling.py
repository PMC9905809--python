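"""Exhaustive combinatorial sampling of groove substitutions.

Every subset of the base->template substitutions defines one variant; with N
polymorphic groove residues there are exactly 2^N variants (for 9 residues,
512).  Each variant's sequence is threaded onto the fixed template backbone,
scored, and ranked by peptide:MHC binding energy (ascending, ties by mask
integer).  The enrichment score of a substitution is the fraction of the
top 2.5% lowest-energy variants that carry it -- 1.0 means the template
residue is present in every top model, 0 means it never helps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

from .design import AlleleSequence, Substitution
from .energy import EnergyParams, InternalScorer, Scorer, ScorerFailure
from .structio import ProcessedTemplate

__all__ = [
    "VariantMask",
    "RankedVariants",
    "EnrichmentTable",
    "MAX_SUBSTITUTIONS",
    "enumerate_variants",
    "score_all",
    "enrichment",
    "threaded_sequence",
]

MAX_SUBSTITUTIONS = 22  # 2^22 ~ 4M variants; guards the exhaustive scorer


@dataclass(frozen=True)
class VariantMask:
    """Subset of substitutions as a bit vector (bit i = substitution i)."""

    bits: tuple[bool, ...]

    @property
    def as_int(self) -> int:
        return sum(1 << i for i, b in enumerate(self.bits) if b)  # little-endian

    @classmethod
    def from_int(cls, value: int, n: int) -> "VariantMask":
        return cls(tuple(bool((value >> i) & 1) for i in range(n)))

    def __str__(self) -> str:
        return format(self.as_int, "x")


@dataclass
class RankedVariants:
    """Variants ordered by ascending binding energy, ties by mask integer."""

    entries: list[tuple[VariantMask, float, float]]  # (mask, E_bind, E_total)
    failures: list[tuple[VariantMask, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class EnrichmentTable:
    """Per-position fraction of the top pool carrying the template residue."""

    score: dict[int, float]  # base-allele substitution position -> [0, 1]
    pool_size: int
    top_fraction: float


def enumerate_variants(subs: Sequence[Substitution]) -> list[VariantMask]:
    """All 2^N substitution subsets in ascending mask-integer order."""
    n = len(subs)
    if n > MAX_SUBSTITUTIONS:
        raise ValueError(
            f"{n} substitutions would enumerate 2^{n} variants; the exhaustive "
            f"internal scorer is capped at {MAX_SUBSTITUTIONS} -- reduce the set "
            "or use an external scorer with stochastic sampling"
        )
    return [VariantMask.from_int(v, n) for v in range(1 << n)]


def threaded_sequence(base_groove_seq: str, subs: Sequence[Substitution],
                      mask: VariantMask) -> str:
    """Groove-frame sequence of one variant (template-frame positions)."""
    seq = list(base_groove_seq)
    for bit, sub in zip(mask.bits, subs):
        if not bit:
            continue
        pos = sub.thread_position
        if not 1 <= pos <= len(seq):
            raise ValueError(f"substitution {sub} outside groove frame (1..{len(seq)})")
        seq[pos - 1] = sub.to_aa
    return "".join(seq)


def score_all(
    template: ProcessedTemplate,
    base_groove_seq: str,
    subs: Sequence[Substitution],
    params: EnergyParams | None = None,
    scorer: Scorer | None = None,
    peptide_sequence: str | None = None,
) -> RankedVariants:
    """Thread and score every substitution subset, then rank.

    ``base_groove_seq`` is the base allele's sequence in the template groove
    frame (mask 0 = pure base).  Per-variant failures of an external scorer
    are recorded and excluded from the ranking; the internal scorer is
    deterministic and never fails.
    """
    scorer = scorer or InternalScorer(params)
    if peptide_sequence is None:
        peptide_sequence = template.peptide.sequence
    masks = enumerate_variants(subs)
    scored: list[tuple[VariantMask, float, float]] = []
    failures: list[tuple[VariantMask, str]] = []
    for mask in masks:
        seq = threaded_sequence(base_groove_seq, subs, mask)
        try:
            e_total, e_bind = scorer(template, seq, peptide_sequence)
        except ScorerFailure as exc:
            failures.append((mask, str(exc)))
            continue
        scored.append((mask, e_bind, e_total))
    scored.sort(key=lambda item: (item[1], item[0].as_int))
    return RankedVariants(entries=scored, failures=failures)


def enrichment(
    ranked: RankedVariants,
    subs: Sequence[Substitution],
    top_fraction: float = 0.025,
) -> EnrichmentTable:
    """Fraction of the top-``top_fraction`` pool carrying each substitution.

    Pool size is ``max(1, ceil(top_fraction * M))`` over the M ranked
    variants (512 variants at 2.5% -> a pool of 13).
    """
    if not ranked.entries:
        raise ValueError("no ranked variants")
    if not 0.0 < top_fraction <= 1.0:
        raise ValueError("top_fraction must be in (0, 1]")
    m = len(ranked.entries)
    pool_size = max(1, math.ceil(top_fraction * m))
    pool = ranked.entries[:pool_size]
    score: dict[int, float] = {}
    for i, sub in enumerate(subs):
        hits = sum(1 for mask, _, _ in pool if mask.bits[i])
        score[sub.position] = hits / pool_size
    return EnrichmentTable(score=score, pool_size=pool_size, top_fraction=top_fraction)
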