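"""Transcript assignment, intensity aggregation, ROI, regions, filters."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from costack.core_io import (
    CHANNEL_PREFIX,
    Frame,
    IntensityStack,
    LabelMask,
    RegionAnnotation,
    TranscriptTable,
)
from costack.errors import ConfigError, FrameMismatchError, ParameterError
from costack.integrate import (
    aggregate_intensities,
    assign_regions,
    assign_transcripts,
    build_cell_table,
    compute_roi_intersection,
    filter_cells,
    restrict_to_roi,
)
from costack.simulate import default_config, rasterize_cells, simulate_tissue


def _tx(frame, rows):
    df = pd.DataFrame(rows, columns=["x", "y", "gene"])
    return TranscriptTable(df, frame)


class TestRoi:
    def test_identical_extents_full_frame(self):
        e = box(0, 0, 100, 100)
        roi = compute_roi_intersection([e, e, e])
        assert roi.equals(e)

    def test_nested_acquisition_regions(self):
        """A 9x9 mm protein acquisition inside a 12x24 mm transcript
        reaction region restricts analysis to the 9x9 window."""
        px_per_mm = 100.0
        st = box(0, 0, 12 * px_per_mm, 24 * px_per_mm)
        sp = box(100, 100, 100 + 9 * px_per_mm, 100 + 9 * px_per_mm)
        roi = compute_roi_intersection([st, sp])
        assert roi.equals(sp)
        assert roi.area == pytest.approx((9 * px_per_mm) ** 2)

    def test_disjoint_extents_error(self):
        with pytest.raises(ConfigError):
            compute_roi_intersection([box(0, 0, 10, 10), box(20, 20, 30, 30)])


class TestAssignTranscripts:
    def test_all_background_unassigned(self, frame):
        mask = LabelMask(np.zeros(frame.shape, dtype=np.int32), frame)
        tx = _tx(frame, [(5.5, 5.5, "A"), (10.2, 12.8, "B")])
        counts, unassigned = assign_transcripts(tx, mask)
        assert unassigned == 2
        assert counts.empty

    def test_point_in_cell_pixel(self, frame):
        arr = np.zeros(frame.shape, dtype=np.int32)
        arr[10:14, 20:24] = 5
        mask = LabelMask(arr, frame)
        tx = _tx(frame, [(22.0, 12.0, "G")])  # centroid pixel of cell 5
        counts, unassigned = assign_transcripts(tx, mask)
        assert unassigned == 0
        assert counts.loc[5, "G"] == 1

    def test_out_of_frame_counted_unassigned(self, frame, caplog):
        arr = np.ones(frame.shape, dtype=np.int32)
        mask = LabelMask(arr, frame)
        tx = _tx(frame, [(-3.0, 2.0, "A"), (1.0, 1.0, "A")])
        with caplog.at_level("WARNING", logger="costack"):
            counts, unassigned = assign_transcripts(tx, mask)
        assert unassigned == 1
        assert counts.loc[1, "A"] == 1

    def test_frame_mismatch_refused(self, frame):
        other = Frame("xenium", frame.shape)
        mask = LabelMask(np.zeros(frame.shape, dtype=np.int32), other)
        tx = _tx(frame, [(1.0, 1.0, "A")])
        with pytest.raises(FrameMismatchError):
            assign_transcripts(tx, mask)

    def test_matches_brute_force_oracle_on_simulation(self):
        """Counts equal a per-point python-loop lookup on a 50-cell tissue,
        and conservation holds."""
        from costack.simulate import draw_cell_molecules, scatter_transcripts

        cfg = default_config(n_cells=50, shape=(256, 256), seed=13)
        truth = simulate_tissue(cfg)
        counts_true, _ = draw_cell_molecules(truth, cfg)
        tx = scatter_transcripts(truth, counts_true, cfg)
        mask = rasterize_cells(truth.cell_polygons, cfg.frame)
        counts, unassigned = assign_transcripts(tx, mask)
        # independent loop oracle
        oracle: dict = {}
        n_un = 0
        for _, row in tx.data.iterrows():
            ix, iy = int(np.floor(row.x)), int(np.floor(row.y))
            if 0 <= ix < 256 and 0 <= iy < 256 and mask.labels[iy, ix] > 0:
                key = (int(mask.labels[iy, ix]), row.gene)
                oracle[key] = oracle.get(key, 0) + 1
            else:
                n_un += 1
        assert unassigned == n_un
        assert counts.to_numpy().sum() + unassigned == len(tx)
        for (cid, gene), v in oracle.items():
            assert counts.loc[cid, gene] == v
        assert counts.to_numpy().sum() == sum(oracle.values())

    def test_conservation_for_every_mask(self, rng, frame):
        tx = _tx(frame, [(x, y, "A") for x, y in rng.uniform(0, 64, (200, 2))])
        for _ in range(5):
            arr = rng.integers(0, 4, size=frame.shape).astype(np.int32)
            counts, unassigned = assign_transcripts(tx, LabelMask(arr, frame))
            assert int(counts.to_numpy().sum()) + unassigned == 200


class TestAggregateIntensities:
    def test_constant_channel(self, frame, rng):
        arr = rng.integers(0, 3, size=frame.shape).astype(np.int32)
        mask = LabelMask(arr, frame)
        stack = IntensityStack(
            ["DAPI"], np.full((1, *frame.shape), 4.25), frame
        )
        means = aggregate_intensities(stack, mask)
        assert np.allclose(means["DAPI"], 4.25)

    def test_single_pixel_cell(self, frame, rng):
        arr = np.zeros(frame.shape, dtype=np.int32)
        arr[7, 9] = 1
        img = rng.uniform(0, 1, size=(1, *frame.shape))
        stack = IntensityStack(["DAPI"], img, frame)
        means = aggregate_intensities(stack, LabelMask(arr, frame))
        assert means.loc[1, "DAPI"] == pytest.approx(img[0, 7, 9], abs=0)

    def test_matches_per_pixel_accumulation_oracle(self, frame, rng):
        arr = rng.integers(0, 6, size=frame.shape).astype(np.int32)
        data = rng.uniform(0, 10, size=(3, *frame.shape))
        stack = IntensityStack(["DAPI", "b", "c"], data, frame)
        means = aggregate_intensities(stack, LabelMask(arr, frame))
        for lab in means.index:
            sel = arr == lab
            for i, ch in enumerate(stack.channels):
                assert abs(means.loc[lab, ch] - data[i][sel].mean()) < 1e-10

    def test_affine_rescaling_equivariance(self, frame, rng):
        arr = rng.integers(0, 4, size=frame.shape).astype(np.int32)
        img = rng.uniform(0, 5, size=(1, *frame.shape))
        m1 = aggregate_intensities(IntensityStack(["DAPI"], img, frame),
                                   LabelMask(arr, frame))
        m2 = aggregate_intensities(IntensityStack(["DAPI"], 3 * img + 2, frame),
                                   LabelMask(arr, frame))
        np.testing.assert_allclose(m2["DAPI"], 3 * m1["DAPI"] + 2, rtol=1e-12)


class TestRegions:
    def _cells(self, pts):
        return pd.DataFrame(
            {"cell_id": range(1, len(pts) + 1),
             "x": [p[0] for p in pts], "y": [p[1] for p in pts]}
        )

    def test_centroid_inside_tumour_square(self, frame):
        regions = RegionAnnotation([("tumour", box(0, 0, 10, 10))], frame)
        out = assign_regions(self._cells([(5, 5)]), regions)
        assert out["region"].iloc[0] == "tumour"

    def test_centroid_outside_all_polygons(self, frame):
        regions = RegionAnnotation([("tumour", box(0, 0, 10, 10))], frame)
        out = assign_regions(self._cells([(50, 50)]), regions)
        assert out["region"].iloc[0] == "none"

    def test_overlap_tie_breaks_to_smallest(self, frame):
        regions = RegionAnnotation(
            [("big", box(0, 0, 40, 40)), ("small", box(10, 10, 20, 20))], frame
        )
        out = assign_regions(self._cells([(15, 15), (5, 5)]), regions)
        assert list(out["region"]) == ["small", "big"]

    def test_membership_matches_ray_casting_oracle(self, frame, rng):
        from shapely.geometry import Polygon

        verts = [(10, 5), (55, 12), (48, 50), (28, 60), (6, 38)]
        poly = Polygon(verts)
        regions = RegionAnnotation([("tumour", poly)], frame)
        pts = rng.uniform(0, 64, size=(200, 2))
        out = assign_regions(self._cells(list(map(tuple, pts))), regions)

        def ray_cast(x, y):  # even-odd rule
            inside = False
            n = len(verts)
            for i in range(n):
                x1, y1 = verts[i]
                x2, y2 = verts[(i + 1) % n]
                if (y1 > y) != (y2 > y):
                    xi = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
                    if x < xi:
                        inside = not inside
            return inside

        expect = ["tumour" if ray_cast(x, y) else "none" for x, y in pts]
        assert list(out["region"]) == expect


class TestFilters:
    @pytest.fixture
    def cells(self):
        return pd.DataFrame(
            {
                "cell_id": [1, 2, 3, 4],
                "x": [1.0] * 4,
                "y": [1.0] * 4,
                "area": [10.0] * 4,
                "gene_A": [0, 10, 5, 21],
                "gene_B": [0, 9, 15, 0],
                CHANNEL_PREFIX + "DAPI": [2.0, 3.0, 4.0, 5.0],
            }
        )

    def test_zero_transcript_exclusion(self, cells):
        out = filter_cells(cells, {"min_total_transcripts": 1})
        assert list(out["cell_id"]) == [2, 3, 4]

    def test_clustering_count_filter_boundary(self, cells):
        # totals are {0, 19, 20, 21}: <20 removes exactly two
        out = filter_cells(cells, {"min_total_transcripts": 20})
        assert list(out["cell_id"]) == [3, 4]

    def test_dapi_filter_noop_when_all_above(self, cells):
        out = filter_cells(cells, {"min_dapi": 1.0})
        pd.testing.assert_frame_equal(out, cells)

    def test_unknown_rule_rejected(self, cells):
        with pytest.raises(ParameterError):
            filter_cells(cells, {"min_banana": 3})


def test_build_cell_table_and_roi(frame, rng):
    arr = np.zeros(frame.shape, dtype=np.int32)
    arr[5:15, 5:15] = 1
    arr[40:50, 40:50] = 2
    mask = LabelMask(arr, frame)
    counts = pd.DataFrame({"A": [3]}, index=pd.Index([1], name="cell_id"))
    inten = pd.DataFrame({"DAPI": [1.5, 2.5]}, index=pd.Index([1, 2], name="cell_id"))
    cells = build_cell_table(mask, counts, inten)
    assert set(cells.columns) >= {"cell_id", "x", "y", "area", "gene_A",
                                  CHANNEL_PREFIX + "DAPI"}
    assert cells.set_index("cell_id").loc[2, "gene_A"] == 0
    roi = box(0, 0, 30, 30)
    kept = restrict_to_roi(cells, roi)
    assert list(kept["cell_id"]) == [1]
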