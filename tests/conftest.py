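import pytest

from oligolens.core import Trajectory
from oligolens.synthetic import (
    BuildRecipe,
    build_ligand,
    build_peptide,
    build_sheet_oligomer,
)
from oligolens.templates import load_default_templates


@pytest.fixture(scope="session")
def templates():
    return load_default_templates()


@pytest.fixture(scope="session")
def hiapp_strand():
    """Single extended hIAPP 20-29 chain (capped)."""
    return build_peptide(BuildRecipe())


@pytest.fixture(scope="session")
def sheet_pair():
    """Two-strand parallel in-register β-sheet."""
    return build_sheet_oligomer(2, BuildRecipe(), registry="parallel")


@pytest.fixture(scope="session")
def helix_ala12():
    return build_peptide(BuildRecipe(
        sequence="AAAAAAAAAAAA", phi_psi=((-57.0, -47.0),) * 12,
        seq_start=1))


@pytest.fixture(scope="session")
def melatonin():
    return build_ligand()


def single_frame_traj(top, frame):
    return Trajectory(topology=top, frames=[frame])


@pytest.fixture(scope="session")
def octamer_small():
    """Small octamer ensemble (20 frames) shared by pipeline-level tests."""
    from oligolens.synthetic import ScenarioSpec, generate_ensemble
    spec = ScenarioSpec(n_peptides=8, n_ligands=0,
                        composition={"beta": 0.25, "coil": 0.5},
                        n_frames=20, seed=42)
    return generate_ensemble(spec)
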