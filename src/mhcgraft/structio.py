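"""Structure input/output and geometric primitives.

Reads pMHC-I (and pMHC-TCR) structures from PDB/mmCIF, extracts the
peptide-binding groove (the first ~180 residues of the heavy chain, i.e. the
alpha-1/alpha-2 domains) together with the bound peptide, renumbers both from
one, and provides the two geometric primitives every downstream stage relies
on: minimum heavy-atom distances and Kabsch superposition / RMSD.

Coordinates and distances are in Angstrom throughout.  Groove positions are
1-based after renumbering; peptide positions are 1-based (P1..Pn).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "StructureModel",
    "ProcessedTemplate",
    "StructureError",
    "read_structure",
    "write_pdb",
    "preprocess_template",
    "min_heavy_atom_distance",
    "superpose_rmsd",
    "kabsch",
]

# one-letter codes for the 20 canonical residues; anything else maps to 'X'
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
ONE_TO_THREE["X"] = "UNK"

CANONICAL_AA = set(THREE_TO_ONE.values())

ChainRole = Literal["heavy", "peptide", "tcr_alpha", "tcr_beta", "light", "other"]

BACKBONE_ATOMS = ("N", "CA", "C", "O")


class StructureError(ValueError):
    """Raised for unreadable, empty or inconsistent structures."""


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coords: np.ndarray  # shape (3,), Angstrom

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise StructureError(f"atom {self.name}: coordinates must be a finite 3-vector")
        object.__setattr__(self, "coords", c)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass(frozen=True)
class Residue:
    seq_id: int
    aa: str  # one-letter, 20 canonical + 'X'
    atoms: tuple[Atom, ...]
    name3: str = ""  # original 3-letter code, kept for writing

    def __post_init__(self) -> None:
        if self.aa not in CANONICAL_AA and self.aa != "X":
            raise StructureError(f"residue {self.seq_id}: invalid amino acid {self.aa!r}")
        object.__setattr__(self, "atoms", tuple(self.atoms))
        if not self.name3:
            object.__setattr__(self, "name3", ONE_TO_THREE[self.aa])

    def heavy_atoms(self) -> tuple[Atom, ...]:
        return tuple(a for a in self.atoms if not a.is_hydrogen)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue]
    role: ChainRole = "other"

    def __post_init__(self) -> None:
        ids = [r.seq_id for r in self.residues]
        if any(b <= a for a, b in zip(ids, ids[1:])):
            raise StructureError(f"chain {self.chain_id}: residues must be ordered by seq_id")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def residue(self, seq_id: int) -> Residue | None:
        for r in self.residues:
            if r.seq_id == seq_id:
                return r
        return None

    def heavy_coords(self) -> np.ndarray:
        pts = [a.coords for r in self.residues for a in r.heavy_atoms()]
        if not pts:
            raise StructureError(f"chain {self.chain_id}: no heavy atoms")
        return np.vstack(pts)


@dataclass
class StructureModel:
    source_id: str
    chains: list[Chain]

    def __post_init__(self) -> None:
        if not self.chains:
            raise StructureError(f"{self.source_id}: structure has no chains")
        ids = [c.chain_id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise StructureError(f"{self.source_id}: duplicate chain ids {ids}")

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise StructureError(f"{self.source_id}: no chain {chain_id!r}")


@dataclass
class ProcessedTemplate:
    """Groove (alpha-1/alpha-2) chain renumbered 1..L plus its peptide (1..n).

    The geometric substrate of all design operations: beta-2-microglobulin,
    the alpha-3 domain, waters and cofactors have been removed.
    """

    groove: Chain
    peptide: Chain
    source_id: str

    def __post_init__(self) -> None:
        if not self.groove.residues or self.groove.residues[0].seq_id != 1:
            raise StructureError("groove numbering must start at 1")
        ids = [r.seq_id for r in self.groove.residues]
        if ids != list(range(1, len(ids) + 1)):
            raise StructureError("groove numbering must be contiguous from 1")
        if len(ids) > 185:
            raise StructureError(f"groove has {len(ids)} residues; expected <= 185")


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def _convert_gemmi_residue(res: gemmi.Residue, seq_id: int) -> Residue:
    # altloc: keep the highest-occupancy conformer per atom name (ties: first
    # listed) -- the source text is silent on this, so the choice is pinned.
    best: dict[str, gemmi.Atom] = {}
    for atom in res:
        prev = best.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            best[atom.name] = atom
    atoms = tuple(
        Atom(a.name, a.element.name, np.array([a.pos.x, a.pos.y, a.pos.z]))
        for a in best.values()
    )
    aa = THREE_TO_ONE.get(res.name, "X")
    return Residue(seq_id=seq_id, aa=aa, atoms=atoms, name3=res.name)


def _is_amino_acid(res: gemmi.Residue) -> bool:
    info = gemmi.find_tabulated_residue(res.name)
    if info is not None and info.is_amino_acid():
        return True
    # unknown names still count as protein if they carry a CA atom
    return info is None and any(a.name == "CA" for a in res)


def read_structure(path: str | Path, format: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Waters and non-protein heteroatoms are dropped at this stage; insertion
    codes are resolved to a strictly increasing internal ``seq_id``; altloc
    groups collapse to the highest-occupancy conformer.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    fmt = {
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
        "auto": gemmi.CoorFormat.Detect,
    }.get(format)
    if fmt is None:
        raise ValueError(f"unknown format {format!r} (pdb, mmcif or auto)")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise StructureError(f"{path}: no models")
    model = st[0]
    chains: list[Chain] = []
    for gchain in model:
        residues: list[Residue] = []
        prev_id = 0
        for gres in gchain:
            if gres.is_water() or not _is_amino_acid(gres):
                continue
            # insertion codes / repeated author numbers -> strictly increasing
            num = gres.seqid.num
            seq_id = num if num > prev_id else prev_id + 1
            residues.append(_convert_gemmi_residue(gres, seq_id))
            prev_id = seq_id
        if residues:
            chains.append(Chain(chain_id=gchain.name, residues=residues))
    if not chains:
        raise StructureError(f"{path}: no protein chains (only waters/heteroatoms?)")
    return StructureModel(source_id=path.stem, chains=chains)


def write_pdb(model: StructureModel | ProcessedTemplate, path: str | Path) -> None:
    """Write a model (or processed template) as a PDB file."""
    if isinstance(model, ProcessedTemplate):
        model = StructureModel(
            source_id=model.source_id,
            chains=[model.groove, model.peptide],
        )
    st = gemmi.Structure()
    st.name = model.source_id
    gm = gemmi.Model("1")
    for chain in model.chains:
        gc = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gr = gemmi.Residue()
            gr.name = res.name3 or ONE_TO_THREE.get(res.aa, "UNK")
            gr.seqid = gemmi.SeqId(res.seq_id, " ")
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.coords)
                ga.occ = 1.0
                gr.add_atom(ga)
            gc.add_residue(gr)
        gm.add_chain(gc)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# template preprocessing
# ---------------------------------------------------------------------------

def _renumber(chain: Chain, role: ChainRole) -> Chain:
    residues = [replace(r, seq_id=i + 1) for i, r in enumerate(chain.residues)]
    return Chain(chain_id=chain.chain_id, residues=residues, role=role)


def preprocess_template(
    model: StructureModel,
    heavy_chain_id: str,
    peptide_chain_id: str,
    groove_span: int = 180,
    reference_seq: str | None = None,
    allow_any_peptide_length: bool = False,
) -> ProcessedTemplate:
    """Retain the alpha-1/alpha-2 domains plus peptide and renumber from 1.

    The groove is operationalized as the first ``groove_span`` residues of the
    mature heavy chain.  If ``reference_seq`` is given, leading residues of
    the heavy chain that precede the reference start (expression tags) are
    stripped by a sequence scan before counting.  All other chains
    (beta-2-microglobulin, alpha-3 is trimmed by the span, TCR chains,
    cofactors, waters) are dropped.
    """
    heavy = model.chain(heavy_chain_id)
    peptide = model.chain(peptide_chain_id)
    if heavy_chain_id == peptide_chain_id:
        raise StructureError("heavy and peptide chains must differ")

    residues = heavy.residues
    if reference_seq:
        # scan for the reference's N-terminal stretch to drop leading tags
        probe = reference_seq[: min(10, len(reference_seq))]
        idx = heavy.sequence.find(probe)
        if idx > 0:
            residues = residues[idx:]
    if len(residues) < groove_span:
        raise StructureError(
            f"heavy chain {heavy_chain_id} has {len(residues)} residues; "
            f"cannot extract a groove of {groove_span}"
        )
    groove = _renumber(
        Chain(chain_id=heavy.chain_id, residues=list(residues[:groove_span])),
        role="heavy",
    )
    pep = _renumber(peptide, role="peptide")
    n = len(pep)
    if not allow_any_peptide_length and not (8 <= n <= 15):
        raise StructureError(
            f"peptide chain {peptide_chain_id} has {n} residues; class I "
            "ligands are 8-15 (pass allow_any_peptide_length=True to override)"
        )
    return ProcessedTemplate(groove=groove, peptide=pep, source_id=model.source_id)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def min_heavy_atom_distance(res: Residue, partner: Chain | Residue) -> float:
    """Minimum Euclidean distance between heavy atoms of ``res`` and ``partner``."""
    a = np.vstack([at.coords for at in res.heavy_atoms()]) if res.heavy_atoms() else None
    if a is None:
        raise StructureError(f"residue {res.seq_id} has no heavy atoms")
    if isinstance(partner, Residue):
        pts = [at.coords for at in partner.heavy_atoms()]
        if not pts:
            raise StructureError(f"residue {partner.seq_id} has no heavy atoms")
        b = np.vstack(pts)
    else:
        b = partner.heavy_coords()
    diff = a[:, None, :] - b[None, :, :]
    return float(np.sqrt(np.min(np.einsum("ijk,ijk->ij", diff, diff))))


def kabsch(mov: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid superposition of ``mov`` onto ``ref``.

    Returns ``(R, t)`` with a proper rotation (det +1) such that
    ``mov @ R.T + t`` minimizes the RMSD to ``ref``.
    """
    if mov.shape != ref.shape or mov.shape[0] < 3:
        raise ValueError("need matched point sets of >= 3 points")
    mc, rc = mov.mean(axis=0), ref.mean(axis=0)
    H = (mov - mc).T @ (ref - rc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    return R, t


FitSelection = Literal["groove_CA"]
RmsdSelection = Literal["peptide_backbone", "peptide_all_heavy", "all"]


def _paired_atoms(
    ref: ProcessedTemplate,
    mov: ProcessedTemplate,
    chain_attr: str,
    atom_filter,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Pair atoms by renumbered seq_id + atom name; report unmatched names."""
    rc: Chain = getattr(ref, chain_attr)
    mc: Chain = getattr(mov, chain_attr)
    ref_pts, mov_pts, unmatched = [], [], []
    mov_index = {r.seq_id: r for r in mc.residues}
    for rres in rc.residues:
        mres = mov_index.get(rres.seq_id)
        for atom in rres.heavy_atoms():
            if not atom_filter(atom):
                continue
            partner = mres.atom(atom.name) if mres else None
            if partner is None or partner.is_hydrogen:
                unmatched.append(f"{chain_attr}:{rres.seq_id}:{atom.name}")
                continue
            ref_pts.append(atom.coords)
            mov_pts.append(partner.coords)
    if not ref_pts:
        return np.empty((0, 3)), np.empty((0, 3)), unmatched
    return np.vstack(ref_pts), np.vstack(mov_pts), unmatched


def superpose_rmsd(
    ref: ProcessedTemplate,
    mov: ProcessedTemplate,
    fit_selection: FitSelection = "groove_CA",
    rmsd_selection: RmsdSelection = "peptide_backbone",
) -> float:
    """Kabsch-fit ``mov`` onto ``ref`` on ``fit_selection`` and report RMSD
    over ``rmsd_selection``.

    Used for peptide-overlay validation: a chimeric structure superposed on
    the wild-type groove C-alpha trace, RMSD measured over peptide backbone
    or all peptide heavy atoms.  Atoms are paired by renumbered seq_id and
    atom name; atoms missing on either side are dropped pairwise.
    """
    if fit_selection != "groove_CA":
        raise ValueError(f"unknown fit selection {fit_selection!r}")
    fit_ref, fit_mov, _ = _paired_atoms(ref, mov, "groove", lambda a: a.name == "CA")
    if fit_ref.shape[0] < 3:
        raise StructureError("fewer than 3 paired groove CA atoms for fitting")
    R, t = kabsch(fit_mov, fit_ref)

    if rmsd_selection == "peptide_backbone":
        sel = [("peptide", lambda a: a.name in BACKBONE_ATOMS)]
    elif rmsd_selection == "peptide_all_heavy":
        sel = [("peptide", lambda a: True)]
    elif rmsd_selection == "all":
        sel = [("groove", lambda a: True), ("peptide", lambda a: True)]
    else:
        raise ValueError(f"unknown rmsd selection {rmsd_selection!r}")

    refs, movs, unmatched = [], [], []
    for chain_attr, flt in sel:
        r, m, u = _paired_atoms(ref, mov, chain_attr, flt)
        refs.append(r)
        movs.append(m)
        unmatched.extend(u)
    ref_pts = np.vstack(refs)
    mov_pts = np.vstack(movs)
    if ref_pts.shape[0] == 0:
        raise StructureError(f"no paired atoms for RMSD; unmatched: {unmatched}")
    moved = mov_pts @ R.T + t
    return float(np.sqrt(np.mean(np.sum((moved - ref_pts) ** 2, axis=1))))
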