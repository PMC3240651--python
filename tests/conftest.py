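import numpy as np
import pytest

from noestar import (
    DynamicsProfile,
    SequenceRecord,
    compute_nhnoe_star,
)
from noestar.simulate import generate_dynamics_profile, p53tad_like_spec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_sequence():
    return SequenceRecord(identifier="toy", residues="MEEPQSDPSV")


@pytest.fixture
def toy_dynamics(toy_sequence):
    """Ten-residue dynamics profile with prolines missing, NHNOE* computed."""
    raw = np.array([-1.2, -0.4, 0.1, np.nan, 0.5, 0.66, -0.5, np.nan, 0.2, -0.8])
    profile = DynamicsProfile(
        residue_numbers=np.arange(1, 11),
        aa=list(toy_sequence.residues),
        noe_raw=raw,
        protein=toy_sequence,
    )
    return compute_nhnoe_star(profile)


@pytest.fixture
def synthetic_dynamics():
    """A 70-residue physics-derived profile with helix-like bumps."""
    spec = p53tad_like_spec(length=70, seed=7)
    return compute_nhnoe_star(generate_dynamics_profile(spec)), spec
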