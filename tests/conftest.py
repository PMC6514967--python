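import numpy as np
import pytest

from metabind import (FrameSet, MetaDParams, PlantedEnsembleSpec,
                      make_binding_system, make_double_well,
                      sample_planted_ensemble)


@pytest.fixture(scope="session")
def double_well():
    """Double well with a 10 kJ/mol basin free-energy difference at 310 K."""
    return make_double_well(delta_f=10.0, barrier=15.0, well_separation=2.0)


@pytest.fixture(scope="session")
def binding_system():
    return make_binding_system(pocket_depth=40.0, decoy_depth=12.0,
                               channel_length=2.0, seed=1)


def five_mode_spec(system, n_frames=5000, seed=0, noise_sd=0.03):
    """The planted five-mode ensemble with the 70/20/5/4/1% populations."""
    from metabind.toy_systems import _LIGAND_TEMPLATE, _place_ligand, _rot_x

    modes = [
        (system.reference_pose, 0.70, noise_sd),
        (np.array(system.metadata["decoy_pose"]), 0.20, noise_sd),
        (_place_ligand([0.3, 0.0, 0.9], _rot_x(np.pi / 2)), 0.05, noise_sd),
        (_place_ligand([-0.3, 0.1, 1.2], np.eye(3)), 0.04, noise_sd),
        (_place_ligand([0.0, -0.3, 1.6], _rot_x(np.pi)), 0.01, noise_sd),
    ]
    return PlantedEnsembleSpec(modes=modes, n_frames=n_frames, seed=seed)


@pytest.fixture(scope="session")
def planted_frames(binding_system):
    return sample_planted_ensemble(binding_system,
                                   five_mode_spec(binding_system, seed=11))


def make_frames(cvs, n_atoms=2, backbone=(0,), ligand=(1,)):
    """Minimal FrameSet with prescribed CV values (coordinates encode the
    CV on the ligand atom's z)."""
    cvs = np.asarray(cvs, dtype=float)
    coords = np.zeros((len(cvs), n_atoms, 3))
    coords[:, 1, 2] = cvs
    return FrameSet(coords, cvs, np.arange(len(cvs), dtype=float),
                    np.zeros(len(cvs), dtype=int),
                    backbone_indices=np.array(backbone),
                    ligand_indices=np.array(ligand))
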