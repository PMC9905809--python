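"""Deterministic synthetic structures, complexes and allele families.

Real groove/peptide/TCR structure collections and allele databases are
large, curated and non-redistributable; every computation in this package
is instead exercised on synthetic fixtures with *planted* ground truth.
A toy complex is two idealized C-alpha traces (3.8 Angstrom spacing)
flanking an extended peptide trace, with one side-chain pseudo-atom per
planned contact placed so the residue's minimum heavy-atom distance to the
partner chain equals the planned value exactly.  Toy grooves are straight
traces, not real helices: contact geometry, not secondary structure, drives
every implemented computation.

Every generator emits a machine-readable ground-truth record consumed
directly by tests, and is a pure function of its spec (identical outputs for
identical specs, byte-identical written files included).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .design import AlleleSequence, Substitution, is_class_change
from .structio import (
    Atom,
    Chain,
    ProcessedTemplate,
    Residue,
    StructureModel,
    preprocess_template,
)

__all__ = [
    "FixtureSpec",
    "ToyComplexTruth",
    "AlleleFamilyTruth",
    "DesignScenario",
    "make_toy_complex",
    "make_allele_family",
    "make_design_scenario",
]

CA_SPACING = 3.8  # Angstrom, consecutive C-alpha distance of an extended trace
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class FixtureSpec:
    """Declarative plan for a synthetic complex / allele family."""

    seed: int = 0
    groove_len: int = 60
    pep_len: int = 9
    contact_plan: list[tuple[int, int, float]] = field(default_factory=list)
    tcr_plan: list[tuple[int, int, float]] = field(default_factory=list)
    polymorphism_plan: list[list[tuple[int, str]]] = field(default_factory=list)
    groove_seq: str | None = None
    pep_seq: str | None = None
    chain_separation: float = 12.0
    pep_offset: int | None = None  # groove position under P1; default: centered
    jitter: float = 0.05

    def __post_init__(self) -> None:
        for plan in (self.contact_plan, self.tcr_plan):
            for g, p, d in plan:
                if d <= 0:
                    raise ValueError(f"planned distance must be positive: {(g, p, d)}")
                if not 1 <= g <= self.groove_len:
                    raise ValueError(f"groove position {g} outside 1..{self.groove_len}")
        for g, p, d in self.contact_plan:
            if not 1 <= p <= self.pep_len:
                raise ValueError(f"peptide position {p} outside 1..{self.pep_len}")


@dataclass
class ToyComplexTruth:
    """Generator-side record of what was planted."""

    contact_plan: list[tuple[int, int, float]]
    tcr_plan: list[tuple[int, int, float]]
    min_dist: dict[int, float]  # groove position -> min planned peptide distance
    cb: dict[str, np.ndarray]  # "A:12" chain:pos -> true CB coordinate
    groove_seq: str
    pep_seq: str


@dataclass
class AlleleFamilyTruth:
    modal_aa: dict[int, str]
    consensus: dict[int, float]  # percent
    hamming: np.ndarray


@dataclass
class DesignScenario:
    """A complete miniature design problem with known outcome.

    The template peptide carries a Lys anchor whose pocket position is Asp
    in the groove allele but Ser in the base (a charge-complementary anchor
    pair, echoing salt-bridge stabilization of a Lys anchor by introduced
    acidic pocket residues), plus one neutral decoy substitution outside the
    interaction shell.  Exhaustive sampling must enrich the anchor
    substitution to 1.0 while the decoy is carried by top variants only by
    chance (0.5 over the full pool).
    """

    template: ProcessedTemplate
    base_allele: AlleleSequence
    groove_allele: AlleleSequence
    substitutions: list[Substitution]
    anchor_position: int
    decoy_position: int
    classes: dict[int, str]
    truth: ToyComplexTruth


def _ideal_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray,
              bond: float = 1.53, angle_deg: float = 110.5) -> np.ndarray:
    """Independent CB construction via the symmetric orthonormal frame.

    Decomposes the CB direction in the (u+v, u-v, normal) frame; kept
    deliberately distinct from the reconstruction route used for scoring so
    fixture ground truth does not share code with the implementation.
    """
    u = (n - ca) / np.linalg.norm(n - ca)
    v = (c - ca) / np.linalg.norm(c - ca)
    e1 = (u + v) / np.linalg.norm(u + v)
    e3 = np.cross(e1, (u - v) / np.linalg.norm(u - v))
    a = 2.0 * math.cos(math.radians(angle_deg)) / np.linalg.norm(u + v)
    c3 = -math.sqrt(max(0.0, 1.0 - a * a))  # sign chosen for L-configuration
    w = a * e1 + c3 * e3
    return ca + bond * w / np.linalg.norm(w)


def _backbone_atoms(ca: np.ndarray, aa: str, mirrored: bool) -> list[Atom]:
    s = -1.0 if mirrored else 1.0
    n_pos = ca + np.array([-1.2 * s, 0.0, 0.5])
    c_pos = ca + np.array([+1.2 * s, 0.0, 0.5])
    atoms = [
        Atom("N", "N", n_pos),
        Atom("CA", "C", ca.copy()),
        Atom("C", "C", c_pos),
    ]
    if aa != "G":
        atoms.append(Atom("CB", "C", _ideal_cb(n_pos, ca, c_pos)))
    return atoms


def _trace_chain(chain_id: str, seqs: str, x0: float, y: float,
                 mirrored: bool, rng: np.random.Generator, jitter: float) -> Chain:
    residues = []
    for i, aa in enumerate(seqs):
        ca = np.array([x0 + CA_SPACING * i, y, 0.0])
        ca = ca + rng.normal(0.0, jitter, size=3)
        residues.append(Residue(seq_id=i + 1, aa=aa, atoms=tuple(_backbone_atoms(ca, aa, mirrored))))
    return Chain(chain_id=chain_id, residues=residues)


def _min_dist_point(q: np.ndarray, pts: np.ndarray) -> float:
    return float(np.min(np.linalg.norm(pts - q, axis=1)))


def _place_contact_atom(groove_res: Residue, target: np.ndarray,
                        partner_pts: np.ndarray, dist: float) -> Atom:
    """Pseudo side-chain atom whose min distance to the partner chain is
    exactly ``dist``, placed along the ray from the target atom toward the
    groove residue's C-alpha."""
    ca = groove_res.atom("CA").coords
    direction = ca - target
    norm = np.linalg.norm(direction)
    if norm < 1e-9:
        raise ValueError("contact target coincides with groove CA")
    u = direction / norm

    def f(t: float) -> float:
        return _min_dist_point(target + t * u, partner_pts) - dist

    hi = norm + dist + 10.0
    if f(hi) < 0:
        raise ValueError(f"infeasible contact plan: cannot reach distance {dist}")
    t = brentq(f, 0.0, hi, xtol=1e-10)
    return Atom("SC", "S", target + t * u)


def make_toy_complex(spec: FixtureSpec) -> tuple[StructureModel, ToyComplexTruth]:
    """Idealized groove/peptide (and optional TCR) complex with planted contacts.

    Chains: ``A`` groove trace at y=0, ``C`` peptide trace at
    y=+chain_separation (backbone mirrored so side chains face the groove),
    and ``T`` a TCR trace at y=-chain_separation when ``tcr_plan`` is given.
    """
    rng = np.random.default_rng(spec.seed)
    groove_seq = spec.groove_seq or "A" * spec.groove_len
    pep_seq = spec.pep_seq or "A" * spec.pep_len
    if len(groove_seq) != spec.groove_len or len(pep_seq) != spec.pep_len:
        raise ValueError("sequence lengths must match groove_len / pep_len")
    offset = spec.pep_offset or (spec.groove_len - spec.pep_len) // 2 + 1

    groove = _trace_chain("A", groove_seq, 0.0, 0.0, False, rng, spec.jitter)
    pep = _trace_chain("C", pep_seq, CA_SPACING * (offset - 1),
                       spec.chain_separation, True, rng, spec.jitter)
    chains = [groove, pep]
    tcr = None
    if spec.tcr_plan:
        tcr_len = max(p for _, p, _ in spec.tcr_plan)
        tcr = _trace_chain("T", "A" * tcr_len, 0.0, -spec.chain_separation,
                           True, rng, spec.jitter)
        chains.append(tcr)

    def plant(plan, partner: Chain) -> None:
        partner_pts = partner.heavy_coords()
        for g, p, d in plan:
            idx = g - 1  # trace residues are 1..L in order
            res = groove.residues[idx]
            pres = partner.residue(p)
            if pres is None:
                raise ValueError(f"planned partner position {p} outside chain {partner.chain_id}")
            target = pres.atom("CA").coords
            atom = _place_contact_atom(res, target, partner_pts, d)
            groove.residues[idx] = Residue(
                seq_id=res.seq_id, aa=res.aa, atoms=res.atoms + (atom,), name3=res.name3
            )

    plant(spec.contact_plan, pep)
    if tcr is not None:
        plant(spec.tcr_plan, tcr)

    # validate the plan actually holds: per-residue min distance to peptide
    planned_min: dict[int, float] = {}
    for g, p, d in spec.contact_plan:
        planned_min[g] = min(planned_min.get(g, math.inf), d)
    from .structio import min_heavy_atom_distance

    for g, d in planned_min.items():
        actual = min_heavy_atom_distance(groove.residue(g), pep)
        if abs(actual - d) > 1e-6:
            raise ValueError(
                f"infeasible contact plan: groove {g} reaches {actual:.3f} A, "
                f"planned {d:.3f} A (contradictory placements?)"
            )

    cb_truth = {
        f"{ch.chain_id}:{r.seq_id}": r.atom("CB").coords
        for ch in chains for r in ch.residues if r.atom("CB") is not None
    }
    truth = ToyComplexTruth(
        contact_plan=list(spec.contact_plan),
        tcr_plan=list(spec.tcr_plan),
        min_dist=planned_min,
        cb=cb_truth,
        groove_seq=groove_seq,
        pep_seq=pep_seq,
    )
    return StructureModel(source_id=f"toy-{spec.seed}", chains=chains), truth


def make_allele_family(spec: FixtureSpec, n_alleles: int) -> tuple[list[AlleleSequence], AlleleFamilyTruth]:
    """Reference allele plus variants realized per polymorphism plan.

    Ground truth (modal residue, consensus %, pairwise Hamming distances) is
    counted directly from the realized sequences by the generator itself.
    """
    if n_alleles < 2:
        raise ValueError("need at least 2 alleles")
    rng = np.random.default_rng(spec.seed)
    length = spec.groove_len
    reference = "".join(rng.choice(list(AA_ALPHABET), size=length))
    seqs = []
    for i in range(n_alleles):
        plan = spec.polymorphism_plan[i] if i < len(spec.polymorphism_plan) else []
        s = list(reference)
        for pos, aa in plan:
            if not 1 <= pos <= length:
                raise ValueError(f"polymorphism position {pos} outside 1..{length}")
            s[pos - 1] = aa
        seqs.append(AlleleSequence(name=f"allele{i:02d}", seq="".join(s)))

    modal: dict[int, str] = {}
    consensus: dict[int, float] = {}
    for p in range(1, length + 1):
        counts: dict[str, int] = {}
        for a in seqs:
            counts[a.residue(p)] = counts.get(a.residue(p), 0) + 1
        m = min(counts, key=lambda x: (-counts[x], x))
        modal[p] = m
        consensus[p] = 100.0 * counts[m] / n_alleles
    H = np.zeros((n_alleles, n_alleles))
    for i in range(n_alleles):
        for j in range(i + 1, n_alleles):
            h = sum(1 for a, b in zip(seqs[i].seq, seqs[j].seq) if a != b)
            H[i, j] = H[j, i] = h
    return seqs, AlleleFamilyTruth(modal_aa=modal, consensus=consensus, hamming=H)


def make_design_scenario(seed: int = 0) -> DesignScenario:
    """Miniature end-to-end design problem with a known enrichment outcome.

    A 20-residue groove trace presents a 9-mer peptide ``GGGGGGGGK``; the
    Lys anchor (P9) sits over groove position 16, which is Asp in the groove
    allele and Ser in the base -- the only energetic inter-chain contact.
    Groove position 4 carries a planted 4.5 Angstrom contact (so groove
    definition picks it up) but its interaction center lies far outside the
    8 Angstrom shell: an Ala->Val decoy there cannot change any energy.
    """
    groove_len, pep_len = 20, 9
    anchor, decoy = 16, 4
    groove_seq = list("G" * groove_len)
    groove_seq[anchor - 1] = "D"
    groove_seq[decoy - 1] = "V"
    base_seq = list("G" * groove_len)
    base_seq[anchor - 1] = "S"
    base_seq[decoy - 1] = "A"

    spec = FixtureSpec(
        seed=seed,
        groove_len=groove_len,
        pep_len=pep_len,
        groove_seq="".join(groove_seq),
        pep_seq="GGGGGGGGK",
        chain_separation=9.0,
        pep_offset=8,  # P1 over groove 8, hence P9 over groove 16
        contact_plan=[(anchor, 9, 3.0), (decoy, 1, 4.5)],
        jitter=0.02,
    )
    model, truth = make_toy_complex(spec)
    template = preprocess_template(model, "A", "C", groove_span=groove_len)
    groove_allele = AlleleSequence("GRV", "".join(groove_seq))
    base_allele = AlleleSequence("BASE", "".join(base_seq))
    subs = [
        Substitution(position=decoy, from_aa="A", to_aa="V", min_dist=4.5,
                     class_change=is_class_change("A", "V"), template_position=decoy),
        Substitution(position=anchor, from_aa="S", to_aa="D", min_dist=3.0,
                     class_change=is_class_change("S", "D"), template_position=anchor),
    ]
    classes = {anchor: "PB", decoy: "PB"}
    return DesignScenario(
        template=template,
        base_allele=base_allele,
        groove_allele=groove_allele,
        substitutions=subs,
        anchor_position=anchor,
        decoy_position=decoy,
        classes=classes,
        truth=truth,
    )
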