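import numpy as np
import pytest

from mhcgraft.fixtures import FixtureSpec, make_design_scenario, make_toy_complex


@pytest.fixture(scope="session")
def design_scenario():
    return make_design_scenario(seed=0)


@pytest.fixture(scope="session")
def toy_complex():
    """Small groove/peptide complex with three planted peptide contacts."""
    spec = FixtureSpec(
        seed=1,
        groove_len=60,
        pep_len=9,
        contact_plan=[(3, 2, 4.0), (5, 3, 3.5), (9, 5, 4.9)],
    )
    return make_toy_complex(spec)


def rigid_transform(rng: np.random.Generator):
    """Random proper rotation + translation (seeded)."""
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    t = rng.uniform(-20, 20, size=3)
    return R, t


def transform_template(template, R, t):
    """Apply a rigid transform to every atom of a processed template."""
    from dataclasses import replace

    from mhcgraft.structio import Atom, Chain, ProcessedTemplate

    def move_chain(chain):
        residues = []
        for res in chain.residues:
            atoms = tuple(
                Atom(a.name, a.element, R @ a.coords + t) for a in res.atoms
            )
            residues.append(replace(res, atoms=atoms))
        return Chain(chain_id=chain.chain_id, residues=residues, role=chain.role)

    return ProcessedTemplate(
        groove=move_chain(template.groove),
        peptide=move_chain(template.peptide),
        source_id=template.source_id,
    )
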