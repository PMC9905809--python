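import numpy as np
import pytest

from conftest import rigid_transform, transform_template
from mhcgraft.design import Substitution
from mhcgraft.energy import (
    EnergyParams,
    ExternalScorer,
    InternalScorer,
    ScorerFailure,
    interaction_centers,
    pair_energy,
    reconstruct_cb,
    thread_and_score,
)
from mhcgraft.fixtures import FixtureSpec, make_toy_complex
from mhcgraft.structio import Chain, ProcessedTemplate, Residue, StructureError, preprocess_template
from oracles import oracle_bind_energy, oracle_centers


@pytest.fixture()
def template(design_scenario):
    return design_scenario.template


class TestInteractionCenters:
    def test_glycine_uses_ca(self, template):
        res = template.groove.residues[0]  # scenario groove is mostly Gly
        assert res.aa == "G"
        centers = interaction_centers(template)
        assert np.allclose(centers["G1"], res.atom("CA").coords)

    def test_cb_used_when_present(self, template):
        anchor = template.groove.residue(16)  # Asp, carries a CB
        assert anchor.aa == "D" and anchor.atom("CB") is not None
        centers = interaction_centers(template)
        assert np.allclose(centers["G16"], anchor.atom("CB").coords)

    def test_missing_cb_reconstructed_close_to_truth(self, design_scenario):
        from dataclasses import replace

        template = design_scenario.template
        truth_cb = design_scenario.truth.cb["A:16"]
        stripped_res = replace(
            template.groove.residue(16),
            atoms=tuple(a for a in template.groove.residue(16).atoms if a.name != "CB"),
        )
        residues = [stripped_res if r.seq_id == 16 else r for r in template.groove.residues]
        stripped = ProcessedTemplate(
            groove=Chain(chain_id="A", residues=residues, role="heavy"),
            peptide=template.peptide,
            source_id=template.source_id,
        )
        centers = interaction_centers(stripped)
        assert np.linalg.norm(centers["G16"] - truth_cb) < 0.05

    def test_missing_backbone_errors(self):
        from mhcgraft.structio import Atom

        res = Residue(1, "A", (Atom("CA", "C", np.zeros(3)),))
        chain = Chain(chain_id="A", residues=[res], role="heavy")
        pep = Chain(
            chain_id="C",
            residues=[
                Residue(i + 1, "G", (Atom("CA", "C", np.array([i * 3.8, 9.0, 0.0])),))
                for i in range(8)
            ],
            role="peptide",
        )
        with pytest.raises(StructureError, match="backbone"):
            interaction_centers(ProcessedTemplate(groove=chain, peptide=pep, source_id="x"))


def test_reconstruct_cb_geometry():
    """Reconstructed CB honours bond length and the two tetrahedral angles."""
    n = np.array([-0.525, 1.363, 0.0])
    ca = np.zeros(3)
    c = np.array([1.526, 0.0, 0.0])
    cb = reconstruct_cb(n, ca, c)
    assert np.linalg.norm(cb - ca) == pytest.approx(1.53, abs=1e-9)
    for other in (n, c):
        u = (other - ca) / np.linalg.norm(other - ca)
        v = (cb - ca) / np.linalg.norm(cb - ca)
        angle = np.degrees(np.arccos(np.clip(u @ v, -1, 1)))
        assert angle == pytest.approx(110.5, abs=1e-6)
    # L-configuration: same side of the N-CA-C plane as the ideal alanine CB
    ideal = np.array([-0.507, -0.771, -1.206])
    assert cb @ np.cross(n - ca, c - ca) > 0
    assert np.linalg.norm(cb - ideal) < 0.05


class TestPairEnergy:
    @pytest.mark.parametrize(
        "aa1,aa2,dist,expected",
        [
            ("K", "D", 5.0, -2.0),   # salt bridge
            ("K", "D", 9.0, 0.0),    # beyond contact cutoff
            ("L", "L", 2.5, 9.0),    # hydrophobic pair inside clash range
            ("K", "R", 5.0, 2.0),    # like charges repel
            ("S", "K", 5.0, -0.5),   # polar-charged
            ("L", "K", 5.0, 0.5),    # hydrophobic-charged
            ("G", "K", 5.0, 0.0),    # special class is inert
            ("L", "S", 5.0, 0.0),    # hydrophobic-polar
            ("X", "K", 2.0, 0.0),    # nonstandard residues never score
        ],
    )
    def test_matrix_and_cutoffs(self, aa1, aa2, dist, expected):
        assert pair_energy(aa1, aa2, dist) == expected

    def test_symmetric(self):
        for pair in [("K", "D"), ("L", "S"), ("A", "R")]:
            assert pair_energy(*pair, 5.0) == pair_energy(*pair[::-1], 5.0)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            pair_energy("K", "D", -1.0)


class TestThreadAndScore:
    def test_distant_chains_score_zero(self):
        spec = FixtureSpec(seed=4, groove_len=20, pep_len=9, chain_separation=25.0,
                           contact_plan=[(10, 5, 4.0)])
        model, _ = make_toy_complex(spec)
        template = preprocess_template(model, "A", "C", groove_span=20)
        vm = thread_and_score(template, "K" * 20, "D" * 9)
        assert vm.E_bind == 0.0

    def test_single_salt_bridge(self, design_scenario):
        template = design_scenario.template
        groove_seq = design_scenario.groove_allele.seq  # Asp at the anchor pocket
        vm = thread_and_score(template, groove_seq)
        assert vm.E_bind == -2.0

    def test_salt_bridge_lowers_binding_energy(self, design_scenario):
        """Asp introduced at the pocket of a Lys anchor strictly lowers E_bind."""
        template = design_scenario.template
        base = design_scenario.base_allele.seq
        asp = base[:15] + "D" + base[16:]
        assert thread_and_score(template, asp).E_bind < thread_and_score(template, base).E_bind

    def test_matches_bruteforce_oracle(self, design_scenario, toy_complex):
        template = design_scenario.template
        truth = design_scenario.truth
        for seq in (design_scenario.base_allele.seq, design_scenario.groove_allele.seq):
            vm = thread_and_score(template, seq)
            centers = oracle_centers(template, truth.cb)
            assert vm.E_bind == pytest.approx(
                oracle_bind_energy(centers, seq, template.peptide.sequence), abs=1e-12
            )
            assert vm.E_total == pytest.approx(
                oracle_bind_energy(centers, seq, template.peptide.sequence, intra=True),
                abs=1e-12,
            )

    def test_rigid_transform_invariance(self, design_scenario):
        template = design_scenario.template
        seq = design_scenario.groove_allele.seq
        e0 = thread_and_score(template, seq).E_bind
        rng = np.random.default_rng(3)
        R, t = rigid_transform(rng)
        moved = transform_template(template, R, t)
        assert thread_and_score(moved, seq).E_bind == pytest.approx(e0, abs=1e-9)

    def test_locality_outside_contact_shell(self, design_scenario):
        """A substitution whose center is outside the shell cannot move E_bind."""
        template = design_scenario.template
        base = design_scenario.base_allele.seq
        decoy = design_scenario.decoy_position
        mutated = base[: decoy - 1] + "V" + base[decoy:]
        assert thread_and_score(template, mutated).E_bind == thread_and_score(template, base).E_bind

    def test_length_mismatch_errors(self, design_scenario):
        with pytest.raises(ValueError, match="length"):
            thread_and_score(design_scenario.template, "KK")

    def test_deterministic(self, design_scenario):
        template = design_scenario.template
        seq = design_scenario.groove_allele.seq
        a = thread_and_score(template, seq)
        b = thread_and_score(template, seq)
        assert a.E_bind == b.E_bind and a.E_total == b.E_total


class TestExternalScorer:
    def test_mock_adapter_passthrough(self, tmp_path, design_scenario):
        script = tmp_path / "mock_scorer.py"
        script.write_text(
            "import json, sys\n"
            "json.dump({'E_total': -12.5, 'E_bind': -7.25}, open(sys.argv[1], 'w'))\n"
        )
        scorer = ExternalScorer(f"python {script} {{out}}")
        e_total, e_bind = scorer(design_scenario.template, design_scenario.base_allele.seq,
                                 "GGGGGGGGK")
        assert (e_total, e_bind) == (-12.5, -7.25)

    def test_failing_adapter_raises_scorer_failure(self, tmp_path, design_scenario):
        script = tmp_path / "bad_scorer.py"
        script.write_text("import sys; sys.exit(3)\n")
        scorer = ExternalScorer(f"python {script} {{out}}")
        with pytest.raises(ScorerFailure, match="exited 3"):
            scorer(design_scenario.template, design_scenario.base_allele.seq, "GGGGGGGGK")

    def test_identical_scores_give_identical_rankings(self, design_scenario):
        from mhcgraft.sampling import score_all

        template = design_scenario.template
        base = design_scenario.base_allele.seq
        subs = design_scenario.substitutions
        internal = InternalScorer()

        def adapter(tpl, groove_seq, pep_seq):
            return internal(tpl, groove_seq, pep_seq)

        ranked_internal = score_all(template, base, subs)
        ranked_adapter = score_all(template, base, subs, scorer=adapter)
        assert [
            (m.as_int, eb, et) for m, eb, et in ranked_internal.entries
        ] == [(m.as_int, eb, et) for m, eb, et in ranked_adapter.entries]
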