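import numpy as np
import pytest

from epishear.network import TrackedTissue
from epishear.synth import SynthScript, generate, generate_sliding_rows, hex_tissue


@pytest.fixture(scope="session")
def hex_static():
    """Static 6x6 hexagonal lattice, two identical frames."""
    return hex_tissue(rows=6, cols=6, n_frames=2)


@pytest.fixture(scope="session")
def affine_video():
    """Jittered lattice under constant pure shear, no events."""
    script = SynthScript(
        rows=10, cols=10, disorder=0.08, n_frames=9, shear_xx=0.3, seed=11
    )
    return generate(script)


@pytest.fixture(scope="session")
def mixed_video():
    """Shear plus one T1, one division, one extrusion (ramped)."""
    probe = SynthScript(rows=12, cols=12, n_frames=2, seed=2)
    t0, _ = generate(probe)
    grid = {v: k for k, v in t0.grid.items()}
    cid = grid[(6, 6)]
    nbr = t0.frames[0].neighbors[cid][0]
    script = SynthScript(
        rows=12,
        cols=12,
        disorder=0.05,
        n_frames=16,
        shear_xx=0.1,
        seed=2,
        events=[
            ("t1", 6, cid, nbr),
            ("division", 8, grid[(4, 4)], 0.3),
            ("extrusion", 10, grid[(8, 8)]),
        ],
    )
    return generate(script)


@pytest.fixture(scope="session")
def sliding_short():
    """Sliding-row video long enough for several T1 cycles."""
    return generate_sliding_rows(
        n_rows=9, n_cols=20, shift_rate=0.6, n_frames=41, seed=3
    )


@pytest.fixture(scope="session")
def grid_of(mixed_video):
    tissue, _ = mixed_video
    return dict(tissue.grid.items())


def strip_events(tissue):
    """Copy of a tissue without T1/extrusion records (lineage kept)."""
    return TrackedTissue(frames=tissue.frames, lineage=tissue.lineage, roi=tissue.roi)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
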