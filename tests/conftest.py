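import numpy as np
import pytest

from ctm.tilemap import LABELS, LymphocyteMap, TileMap


def random_tilemap(rng, n_rows, n_cols, sample_id="S", with_scores=True,
                   labels=LABELS):
    """Uniform random tile map (and score map) for property tests."""
    codes = np.array([LABELS.index(l) for l in labels], dtype=np.int8)
    grid = rng.choice(codes, size=(n_rows, n_cols))
    tmap = TileMap(sample_id, grid)
    if not with_scores:
        return tmap, None
    scores = rng.random((n_rows, n_cols))
    scores[tmap.grid == LABELS.index("empty")] = np.nan
    return tmap, LymphocyteMap(sample_id, scores)


@pytest.fixture
def rng():
    return np.random.default_rng(20230630)
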