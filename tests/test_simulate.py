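"""Ground-truth generator: geometry, molecular statistics, masks, deformation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import nbinom, norm, spearmanr
from shapely import contains_xy

from costack import simulate
from costack.core_io import Frame, PairMap
from costack.errors import CapacityError, ConfigError, ValidityError
from costack.simulate import (
    CellTypeSpec,
    SimConfig,
    default_config,
    deform_polygon,
    draw_cell_molecules,
    landmark_grid,
    make_deformation,
    make_discrepant_masks,
    rasterize_cells,
    simulate_molecules,
    simulate_tissue,
)


def _one_type_config(n_cells, genes, rho, dropout, nb_mean=10.0, theta=2.0,
                     shape=(2048, 2048), seed=0, prot_sd=0.25):
    pairs = PairMap([(g, g + "_p") for g in genes])
    t = CellTypeSpec(
        name="only",
        prevalence=1.0,
        nuclear_radius=5.0,
        cell_radius=9.0,
        gene_means={g: nb_mean for g in genes},
        gene_dispersion=theta,
        protein_means={**{g + "_p": 1.0 for g in genes}, "DAPI": 3.0},
        protein_log_sd=prot_sd,
    )
    return SimConfig(
        frame=Frame("he", shape, 0.5),
        n_cells=n_cells,
        cell_types=[t],
        genes=list(genes),
        channels=[g + "_p" for g in genes] + ["DAPI"],
        pairs=pairs,
        pair_rho={g: r for g, r in zip(genes, rho)},
        dropout={g: d for g, d in zip(genes, dropout)},
        membrane_channel=None,
        seed=seed,
    )


def mc_attenuated_spearman(rho_s, nb_mean, theta, dropout, prot_sd,
                           n=100_000, seed=99):
    """Independent Monte-Carlo oracle for the observable rank correlation.

    Samples the generative model directly (bivariate normal latents, NB
    quantile counts thinned by dropout, log-normal protein) and returns
    the empirical Spearman.
    """
    rng = np.random.default_rng(seed)
    r = 2.0 * np.sin(np.pi * rho_s / 6.0)
    z1 = rng.standard_normal(n)
    z2 = r * z1 + np.sqrt(1 - r**2) * rng.standard_normal(n)
    p = theta / (theta + nb_mean)
    count = nbinom.ppf(norm.cdf(z1), theta, p)
    if dropout > 0:
        count[rng.random(n) < dropout] = 0
    prot = np.exp(prot_sd * z2)
    return float(spearmanr(count, prot).statistic)


class TestTissue:
    def test_single_cell_nucleus_inside_cell(self):
        cfg = default_config(n_cells=1, shape=(64, 64), seed=1)
        truth = simulate_tissue(cfg)
        assert len(truth.cells) == 1
        nuc, cell = truth.nucleus_polygons[1], truth.cell_polygons[1]
        assert cell.contains(nuc)

    def test_zero_tumour_fraction_all_non_tumour(self):
        cfg = default_config(n_cells=50, shape=(256, 256), seed=2)
        cfg.tumour_fraction = 0.0
        truth = simulate_tissue(cfg)
        assert (truth.cells["region"] == "non-tumour").all()

    def test_same_seed_identical_truth(self, small_config):
        t1 = simulate_tissue(small_config)
        t2 = simulate_tissue(small_config)
        pd.testing.assert_frame_equal(t1.cells, t2.cells)
        for cid in t1.cell_polygons:
            assert t1.cell_polygons[cid].equals(t2.cell_polygons[cid])

    def test_infeasible_packing_rejected(self):
        cfg = default_config(n_cells=450, shape=(64, 64), seed=0)
        with pytest.raises(CapacityError):
            simulate_tissue(cfg)

    def test_polygons_inside_frame_and_disjoint(self, small_truth, small_config):
        h, w = small_config.frame.shape
        ids = list(small_truth.cell_polygons)
        for cid in ids:
            minx, miny, maxx, maxy = small_truth.cell_polygons[cid].bounds
            assert minx >= -1e-9 and miny >= -1e-9 and maxx <= w and maxy <= h
        rng = np.random.default_rng(0)
        for _ in range(30):
            a, b = rng.choice(ids, 2, replace=False)
            inter = small_truth.cell_polygons[a].intersection(
                small_truth.cell_polygons[b]
            )
            assert inter.area < 1e-6


class TestMolecules:
    def test_full_dropout_silences_gene(self):
        cfg = _one_type_config(200, ["gA", "gB"], rho=[0.5, 0.5],
                               dropout=[1.0, 0.0], shape=(512, 512))
        truth = simulate_tissue(cfg)
        counts, _ = draw_cell_molecules(truth, cfg)
        assert (counts["gA"] == 0).all()
        assert (counts["gB"] > 0).any()

    def test_nb_mean_within_three_standard_errors(self):
        """Per-cell totals of a zero-dropout gene match the configured NB
        mean at n >= 2000 (tolerance: 3 SE of the NB)."""
        n, mu, theta = 2000, 10.0, 2.0
        cfg = _one_type_config(n, ["g"], rho=[0.0], dropout=[0.0],
                               nb_mean=mu, theta=theta)
        truth = simulate_tissue(cfg)
        counts, _ = draw_cell_molecules(truth, cfg)
        se = np.sqrt((mu + mu**2 / theta) / n)
        assert abs(counts["g"].mean() - mu) < 3 * se

    def test_zero_fraction_at_least_dropout(self):
        d = 0.4
        cfg = _one_type_config(2000, ["g"], rho=[0.0], dropout=[d])
        truth = simulate_tissue(cfg)
        counts, _ = draw_cell_molecules(truth, cfg)
        assert (counts["g"] == 0).mean() >= d - 0.03  # 3 binomial SE

    def test_copula_rank_correlation_matches_mc_oracle(self):
        """Empirical per-cell Spearman of (count, protein) at rho=0.7 and
        zero dropout lands within +/-0.05 of the Monte-Carlo-attenuated
        target."""
        cfg = _one_type_config(5000, ["g"], rho=[0.7], dropout=[0.0])
        truth = simulate_tissue(cfg)
        counts, prot = draw_cell_molecules(truth, cfg)
        got = spearmanr(counts["g"], prot["g_p"]).statistic
        expect = mc_attenuated_spearman(0.7, 10.0, 2.0, 0.0, 0.25)
        assert abs(got - expect) < 0.05

    def test_no_background_means_all_spots_in_cells(self):
        cfg = default_config(n_cells=60, shape=(256, 256), seed=3)
        cfg.background_rate = 0.0
        truth = simulate_tissue(cfg)
        counts, _ = draw_cell_molecules(truth, cfg)
        tx = simulate.scatter_transcripts(truth, counts, cfg)
        pts = tx.data
        covered = np.zeros(len(pts), dtype=bool)
        for poly in truth.cell_polygons.values():
            covered |= contains_xy(poly, pts["x"].to_numpy(), pts["y"].to_numpy())
        assert covered.all()

    def test_unknown_pair_gene_is_config_error(self):
        cfg = _one_type_config(10, ["g"], rho=[0.5], dropout=[0.0],
                               shape=(128, 128))
        with pytest.raises(ConfigError):
            SimConfig(
                frame=cfg.frame, n_cells=10, cell_types=cfg.cell_types,
                genes=cfg.genes, channels=cfg.channels, pairs=cfg.pairs,
                pair_rho={"nope": 0.5}, membrane_channel=None,
            )

    def test_same_seed_identical_molecules(self, small_truth, small_config):
        c1, p1 = draw_cell_molecules(small_truth, small_config)
        c2, p2 = draw_cell_molecules(small_truth, small_config)
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(p1, p2)

    def test_rendered_stack_shapes_and_dapi(self, small_truth, small_config):
        tx, stack = simulate_molecules(small_truth, small_config)
        assert stack.data.shape == (len(small_config.channels), 256, 256)
        assert (stack.data >= 0).all()
        # DAPI concentrates on nuclei: nucleus pixels far brighter than bg
        dapi = stack.channel("DAPI")
        nuc = rasterize_cells(small_truth.nucleus_polygons, small_config.frame)
        assert dapi[nuc.labels > 0].mean() > 5 * dapi[nuc.labels == 0].mean()


class TestDiscrepantMasks:
    def test_zero_expand_shrink_equal_rasterized_truth(self, small_truth):
        a, b = make_discrepant_masks(small_truth, 0.0, 0.0)
        nuc = rasterize_cells(small_truth.nucleus_polygons, small_truth.frame)
        cells = rasterize_cells(small_truth.cell_polygons, small_truth.frame)
        np.testing.assert_array_equal(a.labels, nuc.labels)
        np.testing.assert_array_equal(b.labels, cells.labels)

    def test_area_monotone_in_expand(self, small_truth):
        areas = []
        for e in [0.0, 2.0, 5.0]:
            a, _ = make_discrepant_masks(small_truth, e, 0.0)
            areas.append(np.bincount(a.labels.ravel())[1:])
        for prev, cur in zip(areas, areas[1:]):
            assert (cur >= prev).all()

    def test_mask_areas_bounded_by_truth_and_dilation(self, small_truth):
        """area_B <= rasterized true cell area, and every expanded pixel of
        cell c lies within expand_px of c's nucleus and no closer to any
        other nucleus (brute-force distance check)."""
        e, s = 4.0, 2.0
        a, b = make_discrepant_masks(small_truth, e, s)
        cells = rasterize_cells(small_truth.cell_polygons, small_truth.frame)
        area_true = np.bincount(cells.labels.ravel(), minlength=200)
        area_b = np.bincount(b.labels.ravel(), minlength=200)
        present = np.unique(b.labels)[1:]
        assert (area_b[present] <= area_true[present]).all()

        nuc = rasterize_cells(small_truth.nucleus_polygons, small_truth.frame)
        from scipy import ndimage as ndi

        rng = np.random.default_rng(0)
        labs = rng.choice(list(a.label_set()), 5, replace=False)
        for lab in labs:
            own = ndi.distance_transform_edt(nuc.labels != lab)
            others = ndi.distance_transform_edt((nuc.labels == 0) | (nuc.labels == lab))
            sel = a.labels == lab
            assert own[sel].max() <= e + 1e-9
            # no pixel of lab is strictly closer to another nucleus
            assert (own[sel] <= others[sel] + 1e-9).all()

    def test_full_erosion_drops_cell(self, small_truth):
        _, b = make_discrepant_masks(small_truth, 0.0, 50.0)
        assert len(b.label_set()) < len(small_truth.cell_polygons)


class TestDeformation:
    def test_zero_amplitude_is_identity(self):
        cfg = default_config(seed=4)
        cfg.deform_amplitude = 0.0
        field = make_deformation(cfg)
        pts = np.array([[10.0, 20.0], [400.0, 300.0]])
        np.testing.assert_allclose(field.apply(pts), pts, atol=0)
        train, test = landmark_grid(field, cfg.frame)
        np.testing.assert_allclose(train.src, train.dst, atol=0)

    def test_same_seed_same_field(self):
        cfg = default_config(seed=4)
        f1, f2 = make_deformation(cfg, tag=2), make_deformation(cfg, tag=2)
        pts = np.random.default_rng(0).uniform(0, 512, (50, 2))
        np.testing.assert_allclose(f1.apply(pts), f2.apply(pts), atol=0)

    def test_displacement_bounded_by_amplitude(self):
        cfg = default_config(seed=6)
        cfg.deform_amplitude = 7.5
        field = make_deformation(cfg)
        h, w = cfg.frame.shape
        gx, gy = np.meshgrid(np.linspace(0, w, 64), np.linspace(0, h, 64))
        disp = field.displacement(np.column_stack([gx.ravel(), gy.ravel()]))
        assert np.linalg.norm(disp, axis=1).max() <= 7.5 + 1e-6

    def test_folding_field_rejected(self):
        cfg = default_config(seed=6)
        cfg.deform_amplitude, cfg.deform_scale = 120.0, 12.0
        with pytest.raises(ValidityError):
            make_deformation(cfg)

    def test_landmarks_include_held_out_and_at_least_eight(self):
        cfg = default_config(seed=6)
        field = make_deformation(cfg)
        train, test = landmark_grid(field, cfg.frame, n_grid=3)
        assert len(train) + len(test) >= 8
        assert len(test) >= 1

    def test_deform_polygon_preserves_topology(self, small_truth, small_config):
        field = make_deformation(small_config, tag=0)
        poly = small_truth.cell_polygons[1]
        moved = deform_polygon(field, poly)
        assert moved.is_valid
        assert abs(moved.area - poly.area) / poly.area < 0.5
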