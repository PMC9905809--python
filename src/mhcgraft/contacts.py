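"""Contact-frequency analysis and position classification.

Over a collection of pMHC-I structures, a groove position "contacts" the
peptide in one structure when its minimum heavy-atom distance to the peptide
is within 4 Angstrom; the peptide-contact frequency is the percentage of
structures in which that holds, and likewise for TCR contacts over
pMHC-TCR structures.  Positions are then classified as peptide-only binding
(PB), TCR-only binding (TB), or dual peptide-TCR binding (PTB) with a 10%
frequency cutoff.  Consensus/variability scores over an allele family
complete the picture of which positions can be redesigned safely.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

from .design import AlleleSequence, PairMapping, align_pair
from .structio import Chain, ProcessedTemplate, min_heavy_atom_distance

__all__ = [
    "ContactProfile",
    "PositionClassification",
    "ConsensusProfile",
    "contact_frequency",
    "classify",
    "consensus_scores",
]

Label = Literal["PB", "TB", "PTB", "unclassified"]


@dataclass
class ContactProfile:
    n_structures: int
    freq: dict[int, float]  # position -> percentage in [0, 100]
    contact_counts: dict[int, int]


@dataclass(frozen=True)
class PositionClassification:
    label: Label
    pep_freq: float
    tcr_freq: float


@dataclass
class ConsensusProfile:
    consensus: dict[int, float]  # % frequency of the modal residue
    variability: dict[int, float]  # 100 - consensus
    modal_aa: dict[int, str]


def _as_pair(entry) -> tuple[Chain, Chain]:
    if isinstance(entry, ProcessedTemplate):
        return entry.groove, entry.peptide
    groove, partner = entry
    if isinstance(groove, ProcessedTemplate):
        groove = groove.groove
    return groove, partner


def contact_frequency(
    templates: Sequence,
    threshold: float = 4.0,
    n_positions: int = 180,
) -> ContactProfile:
    """Per-position contact frequency (%) over a structure collection.

    ``templates`` holds either :class:`ProcessedTemplate` objects (peptide
    contacts) or ``(groove_chain, partner_chain)`` pairs, all renumbered to
    the common 1..``n_positions`` frame.  A position absent (disordered) in
    a structure counts as non-contacting in that structure, keeping the
    denominator constant across positions.
    """
    if not templates:
        raise ValueError("empty structure list")
    counts = {p: 0 for p in range(1, n_positions + 1)}
    for i, entry in enumerate(templates):
        groove, partner = _as_pair(entry)
        if partner is None or not partner.residues:
            raise ValueError(f"structure #{i} ({groove.chain_id}): no partner chain")
        for res in groove.residues:
            if res.seq_id > n_positions:
                continue
            if min_heavy_atom_distance(res, partner) <= threshold:
                counts[res.seq_id] += 1
    n = len(templates)
    freq = {p: 100.0 * c / n for p, c in counts.items()}
    return ContactProfile(n_structures=n, freq=freq, contact_counts=counts)


def classify(pep_freq: float, tcr_freq: float, cutoff: float = 10.0,
             tie_label: Label = "PB") -> PositionClassification:
    """Classify a groove position from its contact frequencies.

    PTB when both frequencies exceed the cutoff; PB/TB when only one surface
    is engaged; when both are below the cutoff (but nonzero) the larger
    frequency decides, ties going to ``tie_label``; a frequency exactly at
    the cutoff blocks the "-only" labels and likewise falls through to the
    larger-frequency rule; (0, 0) is unclassified.
    """
    for name, f in (("peptide", pep_freq), ("TCR", tcr_freq)):
        if not 0.0 <= f <= 100.0:
            raise ValueError(f"{name}-contact frequency {f} outside [0, 100]")

    def make(label: Label) -> PositionClassification:
        return PositionClassification(label=label, pep_freq=pep_freq, tcr_freq=tcr_freq)

    if pep_freq == 0.0 and tcr_freq == 0.0:
        return make("unclassified")
    if pep_freq > cutoff and tcr_freq > cutoff:
        return make("PTB")
    if 0.0 < pep_freq < cutoff and 0.0 < tcr_freq < cutoff:
        if pep_freq == tcr_freq:
            return make(tie_label)
        return make("PB" if pep_freq > tcr_freq else "TB")
    if pep_freq > 0.0 and tcr_freq < cutoff:
        return make("PB")
    if tcr_freq > 0.0 and pep_freq < cutoff:
        return make("TB")
    # boundary cases (a frequency exactly at the cutoff): larger wins
    if pep_freq == tcr_freq:
        return make(tie_label)
    return make("PB" if pep_freq > tcr_freq else "TB")


def consensus_scores(
    sequences: Sequence[AlleleSequence],
    reference: AlleleSequence,
    n_positions: int | None = None,
    mappings: Sequence[PairMapping] | None = None,
) -> ConsensusProfile:
    """Consensus (modal-residue frequency, %) per reference position.

    Each sequence is mapped onto the reference frame by global pairwise
    alignment; gaps are excluded from the denominator; modal ties break
    alphabetically.  Positions with zero non-gap coverage are reported as
    missing rather than zero.
    """
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences for a consensus")
    n_positions = n_positions or len(reference)
    if mappings is None:
        mappings = [align_pair(reference, s) for s in sequences]
    elif len(mappings) != len(sequences):
        raise ValueError("mappings must parallel sequences")

    consensus: dict[int, float] = {}
    variability: dict[int, float] = {}
    modal_aa: dict[int, str] = {}
    for p in range(1, n_positions + 1):
        counts: dict[str, int] = {}
        for seq, mapping in zip(sequences, mappings):
            spos = mapping.a_to_b.get(p)
            if spos is None:
                continue
            aa = seq.residue(spos)
            counts[aa] = counts.get(aa, 0) + 1
        total = sum(counts.values())
        if total == 0:
            continue  # zero coverage -> missing, not 0
        modal = min(counts, key=lambda a: (-counts[a], a))
        consensus[p] = 100.0 * counts[modal] / total
        variability[p] = 100.0 - consensus[p]
        modal_aa[p] = modal
    return ConsensusProfile(consensus=consensus, variability=variability, modal_aa=modal_aa)
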