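"""Chimeric groove design: groove definition, allele alignment, substitutions.

The design question: given the structure of a *template* (groove) allele
bound to a desired peptide, and the sequence of a *base* allele whose TCR
surface should be preserved, which base residues must become template
residues so the base framework presents the template's peptide?  The groove
is the set of heavy-chain positions within 5 Angstrom of a peptide heavy
atom; substitutions are the base->template differences at those positions;
the minimal set prunes them using chemical-class changes, enrichment scores
from combinatorial sampling, and a stricter 3.5 Angstrom rule at positions
that also touch the TCR.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .structio import ProcessedTemplate, min_heavy_atom_distance

__all__ = [
    "AlleleSequence",
    "GrooveDefinition",
    "Substitution",
    "ChimeraDesign",
    "PairMapping",
    "CHEMICAL_CLASSES",
    "chemical_class",
    "is_class_change",
    "define_groove",
    "align_pair",
    "build_substitutions",
    "apply_substitutions",
    "minimal_set",
    "read_fasta",
    "parse_substitution_string",
    "format_substitutions",
]

# Chemical classes used for the "charged in place of a neutral residue"
# rule.  class_change requires different classes with a charged class
# involved; "similar residues" means same class.  Configurable partition.
CHEMICAL_CLASSES: dict[str, str] = {}
for _cls, _members in {
    "positive": "KRH",
    "negative": "DE",
    "polar": "STNQYC",
    "hydrophobic": "AVLIMFW",
    "special": "GP",
}.items():
    for _aa in _members:
        CHEMICAL_CLASSES[_aa] = _cls

CHARGED_CLASSES = {"positive", "negative"}


def chemical_class(aa: str, classes: Mapping[str, str] | None = None) -> str:
    table = classes or CHEMICAL_CLASSES
    try:
        return table[aa]
    except KeyError:
        raise ValueError(f"no chemical class for residue {aa!r}") from None


def is_class_change(from_aa: str, to_aa: str, classes: Mapping[str, str] | None = None) -> bool:
    """True when the swap crosses classes with a charged class involved."""
    c1, c2 = chemical_class(from_aa, classes), chemical_class(to_aa, classes)
    return c1 != c2 and bool({c1, c2} & CHARGED_CLASSES)


@dataclass(frozen=True)
class AlleleSequence:
    """A mature MHC-I heavy-chain sequence with its allotype label."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        bad = set(self.seq) - set("ACDEFGHIKLMNPQRSTVWY")
        if bad:
            raise ValueError(f"{self.name}: non-canonical residues {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)

    def residue(self, position: int) -> str:
        """1-based residue lookup."""
        return self.seq[position - 1]


@dataclass
class GrooveDefinition:
    """Groove positions of a template: residues within ``cutoff`` of the peptide.

    ``min_dist`` records the minimum heavy-atom distance to the peptide for
    every groove-frame position (not only those within the cutoff) so the
    stricter 3.5 Angstrom rule for dual peptide/TCR positions can be applied
    later without recomputation.
    """

    template_id: str
    positions: frozenset[int]
    min_dist: dict[int, float]
    cutoff: float = 5.0


@dataclass(frozen=True)
class Substitution:
    """One base->template residue swap, e.g. ``G62Q``.

    ``position`` is in base-allele mature-protein numbering (the reporting
    convention); ``template_position`` is the corresponding template/groove
    structural frame position used for threading.  They coincide when the
    pairwise alignment has no indels.
    """

    position: int
    from_aa: str
    to_aa: str
    min_dist: float = math.inf
    class_change: bool = False
    template_position: int | None = None

    def __post_init__(self) -> None:
        if self.from_aa == self.to_aa:
            raise ValueError(f"substitution at {self.position}: from == to ({self.from_aa})")

    @property
    def thread_position(self) -> int:
        return self.template_position if self.template_position is not None else self.position

    def __str__(self) -> str:
        return f"{self.from_aa}{self.position}{self.to_aa}"


@dataclass
class ChimeraDesign:
    """A base allele carrying the groove substitutions of a template allele."""

    base: AlleleSequence
    groove_allele: AlleleSequence
    substitutions: list[Substitution]
    chimera_seq: str
    name: str


@dataclass
class PairMapping:
    """Position correspondence from a global pairwise alignment (1-based)."""

    a_name: str
    b_name: str
    a_to_b: dict[int, int | None]
    b_to_a: dict[int, int | None]
    score: float

    @property
    def n_gaps(self) -> int:
        return sum(1 for v in self.a_to_b.values() if v is None) + sum(
            1 for v in self.b_to_a.values() if v is None
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def define_groove(template: ProcessedTemplate, cutoff: float = 5.0) -> GrooveDefinition:
    """Groove = heavy-chain residues within ``cutoff`` of a peptide heavy atom."""
    if cutoff <= 0:
        raise ValueError(f"groove cutoff must be positive, got {cutoff}")
    min_dist = {
        res.seq_id: min_heavy_atom_distance(res, template.peptide)
        for res in template.groove.residues
    }
    positions = frozenset(p for p, d in min_dist.items() if d <= cutoff)
    if not positions:
        raise ValueError(
            f"{template.source_id}: no residue within {cutoff} A of the peptide "
            "(peptide chain misassigned?)"
        )
    return GrooveDefinition(
        template_id=template.source_id,
        positions=positions,
        min_dist=min_dist,
        cutoff=cutoff,
    )


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    # end gaps free, as in the EMBOSS Needle default
    aligner.end_gap_score = 0.0
    return aligner


def align_pair(a: AlleleSequence, b: AlleleSequence) -> PairMapping:
    """Global alignment of two allele sequences (BLOSUM62, gap 10/0.5).

    Returns the 1-based position correspondence; positions opposite a gap map
    to ``None``.
    """
    if not a.seq or not b.seq:
        raise ValueError("cannot align empty sequences")
    aligner = _make_aligner()
    alignment = aligner.align(a.seq, b.seq)[0]
    a_to_b: dict[int, int | None] = {i: None for i in range(1, len(a) + 1)}
    b_to_a: dict[int, int | None] = {i: None for i in range(1, len(b) + 1)}
    for (a_start, a_end), (b_start, b_end) in zip(*alignment.aligned):
        for offset in range(a_end - a_start):
            ai, bi = a_start + offset + 1, b_start + offset + 1
            a_to_b[ai] = bi
            b_to_a[bi] = ai
    return PairMapping(
        a_name=a.name, b_name=b.name, a_to_b=a_to_b, b_to_a=b_to_a,
        score=float(alignment.score),
    )


def build_substitutions(
    groove: GrooveDefinition,
    template_allele: AlleleSequence,
    base_allele: AlleleSequence,
    mapping: PairMapping | None = None,
) -> list[Substitution]:
    """Base->template substitutions at polymorphic groove positions.

    Groove positions index the template allele's (structural) frame; output
    positions are reported in base-allele numbering.  Groove positions
    opposite an alignment gap are skipped with a warning.
    """
    if mapping is None:
        mapping = align_pair(template_allele, base_allele)
    subs: list[Substitution] = []
    for tpos in sorted(groove.positions):
        if tpos > len(template_allele):
            raise ValueError(
                f"groove position {tpos} beyond template allele {template_allele.name}"
            )
        bpos = mapping.a_to_b.get(tpos)
        if bpos is None:
            warnings.warn(
                f"groove position {tpos} aligns to a gap in {base_allele.name}; skipped",
                stacklevel=2,
            )
            continue
        t_aa = template_allele.residue(tpos)
        b_aa = base_allele.residue(bpos)
        if t_aa == b_aa:
            continue
        subs.append(
            Substitution(
                position=bpos,
                from_aa=b_aa,
                to_aa=t_aa,
                min_dist=groove.min_dist.get(tpos, math.inf),
                class_change=is_class_change(b_aa, t_aa),
                template_position=tpos,
            )
        )
    return subs


def apply_substitutions(base: AlleleSequence, subs: Sequence[Substitution],
                        groove_allele: AlleleSequence | None = None) -> ChimeraDesign:
    """Apply substitutions to the base sequence, guarding against stale lists."""
    seq = list(base.seq)
    for sub in subs:
        if sub.position < 1 or sub.position > len(seq):
            raise ValueError(f"substitution {sub} outside base sequence")
        if seq[sub.position - 1] != sub.from_aa:
            raise ValueError(
                f"substitution {sub}: base {base.name} has "
                f"{seq[sub.position - 1]!r} at position {sub.position}"
            )
        seq[sub.position - 1] = sub.to_aa
    groove_allele = groove_allele or AlleleSequence("template", base.seq)
    name = f"{groove_allele.name}-{base.name}"
    return ChimeraDesign(
        base=base,
        groove_allele=groove_allele,
        substitutions=list(subs),
        chimera_seq="".join(seq),
        name=name,
    )


def minimal_set(
    subs: Sequence[Substitution],
    enrichment: Mapping[int, float],
    classes: Mapping[int, str] | None = None,
    groove: GrooveDefinition | None = None,
    theta_enrich: float = 0.5,
    ptb_cutoff: float = 3.5,
) -> list[Substitution]:
    """Prune a substitution list to the minimal set.

    A substitution is kept iff it changes chemical character (a charged
    residue replacing a neutral one or vice versa -- always included) or its
    enrichment score reaches ``theta_enrich`` (similar-residue swaps are
    thereby excluded exactly when the sampling gives them no support); and,
    at positions contacting both peptide and TCR (label ``"PTB"`` in
    ``classes``, keyed by base position), only if its minimum heavy-atom
    distance to the peptide is within the stricter ``ptb_cutoff``.

    ``enrichment`` maps base-allele position -> fraction in [0, 1];
    an entry must exist for every substitution.
    """
    classes = classes or {}
    kept: list[Substitution] = []
    for sub in subs:
        if sub.position not in enrichment:
            raise KeyError(f"no enrichment score for substitution {sub}")
        favorable = sub.class_change or enrichment[sub.position] >= theta_enrich
        label = classes.get(sub.position, "PB")
        ptb_ok = label != "PTB" or sub.min_dist <= ptb_cutoff
        if favorable and ptb_ok:
            kept.append(sub)
    return kept


# ---------------------------------------------------------------------------
# sequence / substitution-list serialization
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[AlleleSequence]:
    """Read allele sequences from FASTA (whitespace in headers kept up to '|')."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    return [AlleleSequence(name=r.id, seq=str(r.seq).upper()) for r in records]


def parse_substitution_string(text: str) -> list[Substitution]:
    """Parse compact notation like ``"G62Q,K66N,H70Q"``."""
    subs = []
    for token in text.replace(" ", "").split(","):
        if not token:
            continue
        from_aa, to_aa = token[0], token[-1]
        position = int(token[1:-1])
        subs.append(
            Substitution(position=position, from_aa=from_aa, to_aa=to_aa,
                         class_change=is_class_change(from_aa, to_aa))
        )
    return subs


def format_substitutions(subs: Iterable[Substitution]) -> str:
    return ",".join(str(s) for s in subs)
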