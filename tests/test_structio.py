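import numpy as np
import pytest

from conftest import rigid_transform, transform_template
from mhcgraft.fixtures import FixtureSpec, make_toy_complex
from mhcgraft.structio import (
    Atom,
    Chain,
    ProcessedTemplate,
    Residue,
    StructureError,
    StructureModel,
    min_heavy_atom_distance,
    preprocess_template,
    read_structure,
    superpose_rmsd,
    write_pdb,
)

ONE_RESIDUE_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.697   7.155  -4.974  1.00  0.00           C
END
"""

WATERS_ONLY_PDB = """\
HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O
HETATM    2  O   HOH A   2       3.000   0.000   0.000  1.00  0.00           O
END
"""

ALTLOC_PDB = """\
ATOM      1  N   SER A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA ASER A   1       1.000   0.000   0.000  0.40  0.00           C
ATOM      3  CA BSER A   1       2.000   0.000   0.000  0.60  0.00           C
ATOM      4  C   SER A   1       3.000   0.000   0.000  1.00  0.00           C
END
"""


def _res(seq_id, aa, coords_list, names=None):
    names = names or [f"C{i}" for i in range(len(coords_list))]
    atoms = tuple(Atom(n, "C", np.array(c, float)) for n, c in zip(names, coords_list))
    return Residue(seq_id=seq_id, aa=aa, atoms=atoms)


class TestReadStructure:
    def test_minimal_single_residue(self, tmp_path):
        p = tmp_path / "one.pdb"
        p.write_text(ONE_RESIDUE_PDB)
        model = read_structure(p)
        assert len(model.chains) == 1
        assert len(model.chains[0]) == 1
        assert model.chains[0].residues[0].aa == "A"

    def test_waters_only_is_empty_structure(self, tmp_path):
        p = tmp_path / "wat.pdb"
        p.write_text(WATERS_ONLY_PDB)
        with pytest.raises(StructureError, match="no protein chains"):
            read_structure(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(StructureError, match="no such file"):
            read_structure(tmp_path / "absent.pdb")

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(ALTLOC_PDB)
        model = read_structure(p)
        ca = model.chains[0].residues[0].atom("CA")
        assert ca.coords[0] == pytest.approx(2.0)  # occupancy 0.60 conformer

    def test_round_trip_preserves_sequence_and_coords(self, tmp_path, toy_complex):
        model, _ = toy_complex
        path = tmp_path / "toy.pdb"
        write_pdb(model, path)
        back = read_structure(path)
        for orig_chain in model.chains:
            chain = back.chain(orig_chain.chain_id)
            assert chain.sequence == orig_chain.sequence
            for r0, r1 in zip(orig_chain.residues, chain.residues):
                for a0 in r0.atoms:
                    a1 = r1.atom(a0.name)
                    # PDB coordinate fields carry 3 decimals
                    assert np.allclose(a0.coords, a1.coords, atol=5.1e-4)


class TestPreprocessTemplate:
    def _heavy_chain(self, start, length):
        return Chain(
            chain_id="H",
            residues=[
                _res(start + i, "A", [[i * 3.8, 0, 0], [i * 3.8, 1.5, 0]], ["CA", "CB"])
                for i in range(length)
            ],
        )

    def _pep_chain(self, n=9):
        return Chain(
            chain_id="P",
            residues=[_res(i + 1, "G", [[i * 3.8, 12.0, 0]], ["CA"]) for i in range(n)],
        )

    def test_renumbers_offset_numbering_from_one(self):
        model = StructureModel(
            source_id="fx", chains=[self._heavy_chain(1001, 185), self._pep_chain()]
        )
        tpl = preprocess_template(model, "H", "P", groove_span=180)
        assert [r.seq_id for r in tpl.groove.residues] == list(range(1, 181))
        assert [r.seq_id for r in tpl.peptide.residues] == list(range(1, 10))

    def test_retains_exactly_groove_and_peptide(self):
        extra = Chain(
            chain_id="B",  # a beta-2-microglobulin stand-in, must be dropped
            residues=[_res(i + 1, "V", [[0, -20, i * 3.8]], ["CA"]) for i in range(99)],
        )
        model = StructureModel(
            source_id="fx",
            chains=[self._heavy_chain(1, 200), self._pep_chain(), extra],
        )
        tpl = preprocess_template(model, "H", "P", groove_span=180)
        assert len(tpl.groove) == 180 and len(tpl.peptide) == 9

    def test_short_heavy_chain_errors(self):
        model = StructureModel(
            source_id="fx", chains=[self._heavy_chain(1, 150), self._pep_chain()]
        )
        with pytest.raises(StructureError, match="cannot extract"):
            preprocess_template(model, "H", "P", groove_span=180)

    def test_missing_peptide_chain_errors(self):
        model = StructureModel(source_id="fx", chains=[self._heavy_chain(1, 185)])
        with pytest.raises(StructureError, match="no chain"):
            preprocess_template(model, "H", "P")

    def test_unusual_peptide_length_needs_override(self):
        model = StructureModel(
            source_id="fx", chains=[self._heavy_chain(1, 185), self._pep_chain(n=4)]
        )
        with pytest.raises(StructureError, match="8-15"):
            preprocess_template(model, "H", "P")
        tpl = preprocess_template(model, "H", "P", allow_any_peptide_length=True)
        assert len(tpl.peptide) == 4


class TestMinHeavyAtomDistance:
    def test_two_single_atoms(self):
        r = _res(1, "A", [[0, 0, 0]])
        chain = Chain(chain_id="X", residues=[_res(1, "A", [[0, 0, 4.0]])])
        assert min_heavy_atom_distance(r, chain) == pytest.approx(4.0)

    def test_takes_minimum_over_pairs(self):
        r = _res(1, "A", [[0, 0, 0]])
        chain = Chain(chain_id="X", residues=[_res(1, "A", [[3.2, 0, 0], [7.8, 0, 0]])])
        assert min_heavy_atom_distance(r, chain) == pytest.approx(3.2)

    def test_hydrogens_excluded(self):
        r = Residue(1, "A", (Atom("CA", "C", np.zeros(3)),))
        partner = Chain(
            chain_id="X",
            residues=[
                Residue(
                    1, "A",
                    (Atom("H1", "H", np.array([0.0, 0, 1.0])),
                     Atom("CB", "C", np.array([0.0, 0, 6.0]))),
                )
            ],
        )
        assert min_heavy_atom_distance(r, partner) == pytest.approx(6.0)

    def test_no_heavy_atoms_errors(self):
        r = Residue(1, "A", (Atom("H1", "H", np.zeros(3)),))
        chain = Chain(chain_id="X", residues=[_res(1, "A", [[1, 0, 0]])])
        with pytest.raises(StructureError, match="no heavy atoms"):
            min_heavy_atom_distance(r, chain)

    def test_planted_fixture_distances(self, toy_complex):
        model, truth = toy_complex
        groove, pep = model.chain("A"), model.chain("C")
        for g, d in truth.min_dist.items():
            assert min_heavy_atom_distance(groove.residue(g), pep) == pytest.approx(d, abs=1e-6)


class TestSuperposeRmsd:
    @pytest.fixture()
    def template(self, design_scenario):
        return design_scenario.template

    def test_identity_is_zero(self, template):
        assert superpose_rmsd(template, template) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_invariance(self, template):
        rng = np.random.default_rng(42)
        for _ in range(3):
            R, t = rigid_transform(rng)
            moved = transform_template(template, R, t)
            for sel in ("peptide_backbone", "peptide_all_heavy", "all"):
                assert superpose_rmsd(template, moved, rmsd_selection=sel) == pytest.approx(
                    0.0, abs=1e-6
                )

    def test_single_displaced_atom_closed_form(self, template):
        # displace one peptide backbone atom by 1.0 A -> RMSD = sqrt(1/k)
        from dataclasses import replace

        from mhcgraft.structio import Atom, Chain

        pep = template.peptide
        residues = list(pep.residues)
        r0 = residues[0]
        atoms = tuple(
            Atom(a.name, a.element, a.coords + (np.array([0, 0, 1.0]) if a.name == "N" else 0))
            for a in r0.atoms
        )
        residues[0] = replace(r0, atoms=atoms)
        moved = ProcessedTemplate(
            groove=template.groove,
            peptide=Chain(chain_id=pep.chain_id, residues=residues, role=pep.role),
            source_id=template.source_id,
        )
        k = sum(
            1 for r in pep.residues for a in r.heavy_atoms() if a.name in ("N", "CA", "C", "O")
        )
        expected = np.sqrt(1.0 / k)
        assert superpose_rmsd(template, moved, rmsd_selection="peptide_backbone") == pytest.approx(
            expected, abs=1e-6
        )

    def test_symmetry(self, template):
        rng = np.random.default_rng(7)
        R, t = rigid_transform(rng)
        moved = transform_template(template, R, t)
        # perturb all peptide atoms slightly so the RMSD is nonzero
        from dataclasses import replace

        from mhcgraft.structio import Atom, Chain

        jig = np.random.default_rng(8)
        residues = [
            replace(
                r,
                atoms=tuple(
                    Atom(a.name, a.element, a.coords + jig.normal(0, 0.3, 3)) for a in r.atoms
                ),
            )
            for r in moved.peptide.residues
        ]
        moved = ProcessedTemplate(
            groove=moved.groove,
            peptide=Chain(chain_id="C", residues=residues),
            source_id=moved.source_id,
        )
        ab = superpose_rmsd(template, moved)
        ba = superpose_rmsd(moved, template)
        assert ab == pytest.approx(ba, abs=1e-6)
        assert ab > 0.05

    def test_agrees_with_reference_superimposer(self, template):
        """Cross-check the Kabsch fit against Biopython's SVDSuperimposer."""
        from Bio.SVDSuperimposer import SVDSuperimposer

        from mhcgraft.structio import kabsch

        rng = np.random.default_rng(11)
        ref = rng.normal(0, 10, (25, 3))
        mov = ref @ rigid_transform(rng)[0].T + rng.normal(0, 0.5, (25, 3))
        R, t = kabsch(mov, ref)
        sup = SVDSuperimposer()
        sup.set(ref, mov)
        sup.run()
        fitted = mov @ R.T + t
        rmsd = np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1)))
        assert rmsd == pytest.approx(sup.get_rms(), abs=1e-8)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
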