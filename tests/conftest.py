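import numpy as np
import pytest

from npcensus.config import paper_defaults
from npcensus.matching import build_membrane_decoy
from npcensus.pipeline import build_matchers
from npcensus.synthetic import build_phantom, render_npc

BOX = 72
VOXEL = 2.0


@pytest.fixture(scope="session")
def ring_matchers():
    """Rotated-template matcher caches for the three rings (72-voxel box)."""
    return build_matchers(paper_defaults(), box_voxels=BOX)


@pytest.fixture(scope="session")
def decoy_matcher():
    return build_membrane_decoy(VOXEL, (BOX,) * 3)


@pytest.fixture(scope="session")
def clean_c8_render():
    """A complete eight-fold phantom rendered noise-free at 2 nm voxels."""
    return render_npc(build_phantom(8, 95.0), BOX, VOXEL)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
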