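"""Deterministic fixed-backbone scoring of threaded groove sequences.

The design workflow needs, for every combinatorial variant, a peptide:MHC
binding energy to rank by.  This module provides a desk-scale, fully
deterministic statistical contact potential over side-chain interaction
centers: residues interact through their C-beta positions (C-alpha for
glycine), pairs within 8 Angstrom score by a symmetric 5x5 chemical-class
matrix (salt bridges favorable, like charges unfavorable, hydrophobic
packing mildly favorable), and near-overlapping centers incur a clash
penalty.  Because the backbone is fixed, the centers depend only on template
geometry -- threading a new sequence changes which class is assigned to each
center, never where the centers are.

Energy units are arbitrary: the workflow consumes rankings, not physical
binding free energies.  An adapter contract lets users plug in an external
all-atom scorer per variant without changing the pipeline.
"""

from __future__ import annotations

import json
import math
import shlex
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Protocol, Sequence

import numpy as np

from .design import CHEMICAL_CLASSES
from .structio import Chain, ProcessedTemplate, StructureError, write_pdb

__all__ = [
    "EnergyParams",
    "VariantModel",
    "interaction_centers",
    "reconstruct_cb",
    "pair_energy",
    "thread_and_score",
    "Scorer",
    "InternalScorer",
    "ExternalScorer",
    "ScorerFailure",
]

_CLASSES = ("positive", "negative", "polar", "hydrophobic", "special")


def _default_matrix() -> dict[tuple[str, str], float]:
    m: dict[tuple[str, str], float] = {}

    def put(c1: str, c2: str, value: float) -> None:
        m[(c1, c2)] = value
        m[(c2, c1)] = value

    for c1 in _CLASSES:
        for c2 in _CLASSES:
            m[(c1, c2)] = 0.0
    put("positive", "negative", -2.0)
    put("positive", "positive", +2.0)
    put("negative", "negative", +2.0)
    put("hydrophobic", "hydrophobic", -1.0)
    put("polar", "polar", -0.5)
    put("polar", "positive", -0.5)
    put("polar", "negative", -0.5)
    put("hydrophobic", "positive", +0.5)
    put("hydrophobic", "negative", +0.5)
    # special (Gly/Pro) with anything, and hydrophobic-polar, stay 0
    return m


@dataclass
class EnergyParams:
    """Parameters of the contact potential (arbitrary energy units).

    ``contact_cutoff`` bounds the interaction-center distance for a pair to
    score at all; ``clash_cutoff`` adds ``clash_penalty`` to pairs whose
    centers nearly overlap; ``intra_min_separation`` excludes bonded and
    near-bonded intra-chain pairs from the total energy.
    """

    class_matrix: dict[tuple[str, str], float] = field(default_factory=_default_matrix)
    contact_cutoff: float = 8.0
    clash_cutoff: float = 3.0
    clash_penalty: float = 10.0
    intra_min_separation: int = 3

    def __post_init__(self) -> None:
        if self.contact_cutoff <= 0 or self.clash_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        if self.clash_cutoff >= self.contact_cutoff:
            raise ValueError("clash_cutoff must be below contact_cutoff")
        for (c1, c2), v in self.class_matrix.items():
            if self.class_matrix.get((c2, c1)) != v:
                raise ValueError(f"class matrix not symmetric at ({c1}, {c2})")

    @classmethod
    def from_dict(cls, data: Mapping) -> "EnergyParams":
        kwargs = dict(data)
        matrix = kwargs.pop("class_matrix", None)
        params = cls(**kwargs)
        if matrix:
            for key, value in matrix.items():
                c1, c2 = key.split(":") if isinstance(key, str) else key
                params.class_matrix[(c1, c2)] = float(value)
                params.class_matrix[(c2, c1)] = float(value)
        return params


@dataclass
class VariantModel:
    """One scored member of the combinatorial set."""

    mask: tuple[bool, ...]
    sequence: str  # threaded groove sequence
    peptide_sequence: str
    centers: dict[str, np.ndarray]  # "G12"/"P3" -> 3-vector
    E_total: float
    E_bind: float


# ---------------------------------------------------------------------------
# interaction centers
# ---------------------------------------------------------------------------

def reconstruct_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray,
                   bond: float = 1.53, angle_deg: float = 110.5) -> np.ndarray:
    """Ideal C-beta position from backbone N, CA, C.

    Places CB at ``bond`` Angstrom from CA with equal N-CA-CB and C-CA-CB
    angles of ``angle_deg``, on the side of the N-CA-C plane that gives the
    L-configuration.
    """
    u = n - ca
    u /= np.linalg.norm(u)
    v = c - ca
    v /= np.linalg.norm(v)
    d = float(u @ v)
    cos_t = math.cos(math.radians(angle_deg))
    alpha = cos_t / (1.0 + d)
    norm2 = alpha * alpha * (2.0 + 2.0 * d)
    if norm2 > 1.0:
        raise StructureError("degenerate backbone geometry for CB reconstruction")
    beta = math.sqrt((1.0 - norm2) / (1.0 - d * d))
    w = alpha * (u + v) + beta * np.cross(u, v)
    return ca + bond * w


def interaction_centers(template: ProcessedTemplate) -> dict[str, np.ndarray]:
    """Side-chain interaction center per residue: CB, CA for Gly,
    or an ideal CB reconstructed from N/CA/C when CB is absent.

    Keys are ``"G<pos>"`` for groove and ``"P<pos>"`` for peptide residues.
    """
    centers: dict[str, np.ndarray] = {}
    for prefix, chain in (("G", template.groove), ("P", template.peptide)):
        for res in chain.residues:
            ca = res.atom("CA")
            if res.aa == "G":
                if ca is None:
                    raise StructureError(f"residue {prefix}{res.seq_id}: missing CA")
                centers[f"{prefix}{res.seq_id}"] = ca.coords
                continue
            cb = res.atom("CB")
            if cb is not None:
                centers[f"{prefix}{res.seq_id}"] = cb.coords
                continue
            n, cc = res.atom("N"), res.atom("C")
            if ca is None or n is None or cc is None:
                raise StructureError(
                    f"residue {prefix}{res.seq_id}: missing backbone atoms for CB reconstruction"
                )
            centers[f"{prefix}{res.seq_id}"] = reconstruct_cb(n.coords, ca.coords, cc.coords)
    return centers


# ---------------------------------------------------------------------------
# pair potential and threading
# ---------------------------------------------------------------------------

def pair_energy(aa1: str, aa2: str, dist: float, params: EnergyParams | None = None) -> float:
    """Class-pair contact energy for two residues at center distance ``dist``."""
    params = params or EnergyParams()
    if dist < 0:
        raise ValueError("distance must be non-negative")
    if aa1 == "X" or aa2 == "X":
        return 0.0  # nonstandard residues are retained geometrically, never scored
    if dist > params.contact_cutoff:
        return 0.0
    c1, c2 = CHEMICAL_CLASSES[aa1], CHEMICAL_CLASSES[aa2]
    e = params.class_matrix[(c1, c2)]
    if dist < params.clash_cutoff:
        e += params.clash_penalty
    return e


def thread_and_score(
    template: ProcessedTemplate,
    groove_sequence: str,
    peptide_sequence: str | None = None,
    params: EnergyParams | None = None,
    mask: Sequence[bool] = (),
) -> VariantModel:
    """Thread a groove sequence onto the fixed template backbone and score it.

    ``E_bind`` is the sum of pair energies over all peptide-groove center
    pairs; ``E_total`` adds intra-chain pairs separated by at least
    ``intra_min_separation`` in sequence.  Identical inputs give bit-identical
    outputs.
    """
    params = params or EnergyParams()
    L = len(template.groove.residues)
    n = len(template.peptide.residues)
    if peptide_sequence is None:
        peptide_sequence = template.peptide.sequence
    if len(groove_sequence) != L:
        raise ValueError(f"groove sequence length {len(groove_sequence)} != template {L}")
    if len(peptide_sequence) != n:
        raise ValueError(f"peptide sequence length {len(peptide_sequence)} != template {n}")

    centers = interaction_centers(template)
    g_xyz = np.vstack([centers[f"G{i}"] for i in range(1, L + 1)])
    p_xyz = np.vstack([centers[f"P{i}"] for i in range(1, n + 1)])

    def dist_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        diff = a[:, None, :] - b[None, :, :]
        return np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))

    d_inter = dist_matrix(p_xyz, g_xyz)
    e_bind = 0.0
    for i in range(n):
        for j in range(L):
            if d_inter[i, j] <= params.contact_cutoff:
                e_bind += pair_energy(
                    peptide_sequence[i], groove_sequence[j], d_inter[i, j], params
                )

    e_total = e_bind
    for seq, xyz in ((groove_sequence, g_xyz), (peptide_sequence, p_xyz)):
        m = len(seq)
        d_intra = dist_matrix(xyz, xyz)
        for i in range(m):
            for j in range(i + params.intra_min_separation, m):
                if d_intra[i, j] <= params.contact_cutoff:
                    e_total += pair_energy(seq[i], seq[j], d_intra[i, j], params)

    return VariantModel(
        mask=tuple(bool(b) for b in mask),
        sequence=groove_sequence,
        peptide_sequence=peptide_sequence,
        centers=centers,
        E_total=e_total,
        E_bind=e_bind,
    )


# ---------------------------------------------------------------------------
# scorer contract
# ---------------------------------------------------------------------------

class ScorerFailure(RuntimeError):
    """A per-variant scorer failure; the pipeline records it and continues."""


class Scorer(Protocol):
    def __call__(self, template: ProcessedTemplate, groove_sequence: str,
                 peptide_sequence: str) -> tuple[float, float]:
        """Return ``(E_total, E_bind)`` for one variant."""
        ...


class InternalScorer:
    """Default scorer backed by :func:`thread_and_score`."""

    def __init__(self, params: EnergyParams | None = None) -> None:
        self.params = params or EnergyParams()

    def __call__(self, template: ProcessedTemplate, groove_sequence: str,
                 peptide_sequence: str) -> tuple[float, float]:
        vm = thread_and_score(template, groove_sequence, peptide_sequence, self.params)
        return vm.E_total, vm.E_bind


class ExternalScorer:
    """Adapter invoking an external executable per variant.

    ``command_template`` is a shell-style command with placeholders
    ``{template}`` (PDB path), ``{groove_seq}``, ``{peptide_seq}`` and
    ``{out}``; the executable must write JSON ``{"E_total": x, "E_bind": y}``
    to ``{out}``.  A nonzero exit or unparseable output raises
    :class:`ScorerFailure` for that variant only.
    """

    def __init__(self, command_template: str, workdir: str | Path | None = None) -> None:
        self.command_template = command_template
        self.workdir = Path(workdir) if workdir else None

    def __call__(self, template: ProcessedTemplate, groove_sequence: str,
                 peptide_sequence: str) -> tuple[float, float]:
        with tempfile.TemporaryDirectory(dir=self.workdir) as tmp:
            tmp_path = Path(tmp)
            pdb_path = tmp_path / "template.pdb"
            out_path = tmp_path / "scores.json"
            write_pdb(template, pdb_path)
            cmd = self.command_template.format(
                template=pdb_path, groove_seq=groove_sequence,
                peptide_seq=peptide_sequence, out=out_path,
            )
            try:
                proc = subprocess.run(
                    shlex.split(cmd), capture_output=True, text=True, check=False
                )
            except OSError as exc:
                raise ScorerFailure(f"adapter could not start: {exc}") from exc
            if proc.returncode != 0:
                raise ScorerFailure(
                    f"adapter exited {proc.returncode}: {proc.stderr.strip()[:500]}"
                )
            try:
                data = json.loads(out_path.read_text())
                return float(data["E_total"]), float(data["E_bind"])
            except (OSError, ValueError, KeyError) as exc:
                raise ScorerFailure(f"adapter output unreadable: {exc}") from exc
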