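"""Tile-map data model and long-table round trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from ctm.tilemap import (
    LABELS,
    LymphocyteMap,
    TileGeometry,
    TileMap,
    read_cohort,
    read_tilemap,
    validate_cohort,
    write_tilemap,
)

from conftest import random_tilemap


def _write_long(path, rows, header="sample_id\trow\tcol\ttexture\tlymphocyte_score"):
    path.write_text(header + "\n" + "\n".join(rows) + "\n")


class TestReadTilemap:
    def test_direct_reconstruction(self, tmp_path):
        f = tmp_path / "m.tsv"
        _write_long(f, [
            "S\t0\t0\tcancer\t0.5",
            "S\t0\t1\tcancer\t0.25",
            "S\t1\t0\tstroma\t0.1",
            "S\t1\t1\tempty\t",
        ])
        tmap, lmap = read_tilemap(f)
        assert tmap.labels.tolist() == [["cancer", "cancer"], ["stroma", "empty"]]
        assert lmap.grid[0, 0] == 0.5
        assert np.isnan(lmap.grid[1, 1])

    def test_unlisted_positions_fill_as_empty(self, tmp_path):
        f = tmp_path / "m.tsv"
        _write_long(f, ["S\t0\t0\tcancer\t0.9"])
        tmap, _ = read_tilemap(f, n_rows=2, n_cols=2)
        assert tmap.labels[0, 0] == "cancer"
        assert (tmap.labels.ravel().tolist().count("empty")) == 3

    def test_unknown_texture_label_is_an_error(self, tmp_path):
        f = tmp_path / "m.tsv"
        _write_long(f, ["S\t0\t0\ttumor\t0.5"])
        with pytest.raises(ValueError, match="unknown texture label 'tumor'"):
            read_tilemap(f)

    def test_duplicate_position_is_an_error(self, tmp_path):
        f = tmp_path / "m.tsv"
        _write_long(f, ["S\t0\t0\tcancer\t0.5", "S\t0\t0\tstroma\t0.4"])
        with pytest.raises(ValueError, match="duplicate tile position"):
            read_tilemap(f)

    def test_score_out_of_range_is_an_error(self, tmp_path):
        f = tmp_path / "m.tsv"
        _write_long(f, ["S\t0\t0\tcancer\t1.5"])
        with pytest.raises(ValueError, match=r"lymphocyte_score outside \[0, 1\]"):
            read_tilemap(f)

    def test_row_order_does_not_matter(self, tmp_path, rng):
        tmap, lmap = random_tilemap(rng, 6, 5)
        f = tmp_path / "m.tsv"
        write_tilemap(tmap, lmap, f)
        df = pd.read_csv(f, sep="\t")
        shuffled = tmp_path / "shuffled.tsv"
        df.sample(frac=1, random_state=0).to_csv(shuffled, sep="\t", index=False)
        assert read_tilemap(shuffled)[0] == tmap


class TestRoundTrip:
    # file names are unique per generated input, so sharing tmp_path is safe
    @settings(max_examples=30, deadline=None, derandomize=True,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    @given(
        n_rows=st.integers(1, 8),
        n_cols=st.integers(1, 8),
        seed=st.integers(0, 2**16),
    )
    def test_roundtrip_identity(self, tmp_path, n_rows, n_cols, seed):
        rng = np.random.default_rng(seed)
        tmap, lmap = random_tilemap(rng, n_rows, n_cols)
        f = tmp_path / f"rt_{n_rows}_{n_cols}_{seed}.tsv"
        write_tilemap(tmap, lmap, f)
        tmap2, lmap2 = read_tilemap(f)
        assert tmap2 == tmap
        assert np.allclose(lmap2.grid, lmap.grid, equal_nan=True)

    def test_single_tile_map(self, tmp_path):
        tmap = TileMap.from_labels("S", [["cancer"]])
        lmap = LymphocyteMap("S", np.array([[0.3]]))
        f = tmp_path / "one.tsv"
        write_tilemap(tmap, lmap, f)
        assert len(f.read_text().strip().splitlines()) == 2  # header + 1 row
        assert read_tilemap(f)[0] == tmap

    def test_shape_mismatch_rejected(self, tmp_path, rng):
        tmap, _ = random_tilemap(rng, 3, 3, with_scores=False)
        lmap = LymphocyteMap("S", np.zeros((2, 2)))
        with pytest.raises(ValueError, match="shape mismatch"):
            write_tilemap(tmap, lmap, tmp_path / "x.tsv")


class TestValidation:
    def test_score_range_and_geometry_invariants(self):
        with pytest.raises(ValueError):
            LymphocyteMap("S", np.array([[1.2]]))
        with pytest.raises(ValueError):
            TileGeometry(tile_size_px=0)
        with pytest.raises(ValueError):
            TileMap("S", np.zeros((0, 3), dtype=np.int8))

    def test_validate_cohort_reports_mismatches(self, rng):
        cohort = pd.DataFrame(
            {
                "sample_id": ["a", "b", "c"],
                "centre_id": ["X", "X", "Y"],
                "microns_per_px": [0.25, 0.25, 0.25],
            }
        )
        maps = [random_tilemap(rng, 2, 2, sid, with_scores=False)[0]
                for sid in ("a", "b")]
        report = validate_cohort(cohort, maps)
        assert report["missing_map"] == ["c"]
        assert report["orphan_map"] == []
        orphan = random_tilemap(rng, 2, 2, "z", with_scores=False)[0]
        report = validate_cohort(cohort, maps + [orphan])
        assert report["orphan_map"] == ["z"]

    def test_validate_cohort_clean_inputs(self, rng):
        cohort = pd.DataFrame(
            {"sample_id": ["a"], "centre_id": ["X"], "microns_per_px": [0.25]}
        )
        maps = [random_tilemap(rng, 2, 2, "a", with_scores=False)[0]]
        report = validate_cohort(cohort, maps)
        assert report["missing_map"] == [] and report["orphan_map"] == []

    def test_png_export_with_legend(self, tmp_path, rng):
        from PIL import Image

        from ctm.tilemap import CODE, export_png

        tmap, _ = random_tilemap(rng, 5, 7, with_scores=False)
        out = export_png(tmap, tmp_path / "m.png")
        img = np.asarray(Image.open(out))
        assert img.shape == (5, 7)
        assert np.array_equal(img, tmap.grid)
        import json

        legend = json.loads((tmp_path / "m.png.legend.json").read_text())
        assert legend == CODE

    def test_declared_bounding_box_must_cover_tiles(self, tmp_path):
        f = tmp_path / "m.tsv"
        _write_long(f, ["S\t3\t3\tcancer\t0.5"])
        with pytest.raises(ValueError, match="bounding box"):
            read_tilemap(f, n_rows=2, n_cols=2)

    def test_read_cohort_rejects_duplicates(self, tmp_path):
        f = tmp_path / "cohort.tsv"
        f.write_text(
            "sample_id\tcentre_id\tmicrons_per_px\na\tX\t0.25\na\tX\t0.25\n"
        )
        with pytest.raises(ValueError, match="duplicate sample_id"):
            read_cohort(f)
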