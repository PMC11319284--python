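"""Geometry, fibroblast gradient, heterogeneity sampling and coupling-map
construction."""

import numpy as np
import pytest
from scipy import stats

from sanfib import tissue_generator as tg


class TestGeometry:
    def test_default_full_scale_layout(self):
        geom = tg.build_geometry(tg.full_preset())
        assert geom.type_map.shape == (200, 200)
        assert len(geom.seps) == 5
        ids = [s.sep_id for s in geom.seps]
        assert ids == [1, 2, 3, 4, 5]            # numbered top to bottom
        rows = [s.center_row for s in geom.seps]
        assert rows == sorted(rows)
        for s in geom.seps:
            assert s.col_exit - s.col_start == 20
            assert s.row1 - s.row0 == 11
            # the channel is 20 x width cells of nodal tissue
            block = geom.type_map[s.row0:s.row1, s.col_start:s.col_exit]
            assert np.all(block == tg.SAN)

    def test_pathway_physical_length(self):
        geom = tg.build_geometry(tg.full_preset())
        s = geom.seps[0]
        length_mm = (s.col_exit - s.col_start) * tg.CELL_LENGTH_UM * 1e-3
        assert length_mm == pytest.approx(1.34)

    @pytest.mark.parametrize("width", [7, 15, 19])
    def test_alternative_widths(self, width):
        geom = tg.build_geometry(tg.full_preset(sep_width=width))
        for s in geom.seps:
            assert s.row1 - s.row0 == width

    def test_san_fully_insulated_without_pathways(self):
        cfg = tg.GeometryConfig(n_seps=0)
        geom = tg.build_geometry(cfg)
        tm = geom.type_map
        # every SAN cell's 4-neighbourhood contains only SAN or insulator
        rr, cc = np.nonzero(tm == tg.SAN)
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            neigh = tm[rr + dr, cc + dc]
            assert not np.any(neigh == tg.ATRIAL)

    def test_oversized_ellipse_rejected(self):
        with pytest.raises(ValueError):
            tg.build_geometry(tg.GeometryConfig(nrows=100, ncols=100,
                                                center=(50, 50)))

    def test_too_wide_pathways_rejected(self):
        with pytest.raises(ValueError):
            tg.build_geometry(tg.GeometryConfig(sep_width=40))

    def test_mosaic_gradient(self):
        cfg = tg.full_preset(mosaic=True)
        geom = tg.build_geometry(cfg, seed=3)
        fracs = []
        for s in geom.seps:
            block = geom.type_map[s.row0:s.row1, s.col_start:s.col_exit]
            fracs.append((block == tg.ATRIAL).mean(axis=0))
        fracs = np.mean(fracs, axis=0)
        # probability of an atrial cell rises from the nodal to atrial end
        assert fracs[:5].mean() < 0.35 < 0.65 < fracs[-5:].mean()


class TestFibroblastPlacement:
    @pytest.fixture(scope="class")
    def placed(self):
        geom = tg.build_geometry(tg.full_preset())
        return [tg.place_fibroblasts(geom, seed=s) for s in range(1, 6)]

    def test_central_density_recovered(self, placed):
        fracs = []
        for g in placed:
            mask = g.san_region_mask()
            cells = g.type_map[mask]
            fracs.append(np.mean(cells == tg.FIBROBLAST))
        assert np.mean(fracs) == pytest.approx(0.457, abs=0.02)

    def test_pathway_density_lower_than_centre(self, placed):
        fracs = []
        for g in placed:
            m = g.sep_region_mask()
            cells = g.type_map[m]
            fracs.append(np.mean(cells == tg.FIBROBLAST))
        assert 0.457 - 0.163 < np.mean(fracs) < 0.457
        assert np.mean(fracs) == pytest.approx(0.277, abs=0.05)

    def test_remaining_atrium_fibroblast_free(self, placed):
        for g in placed:
            col_zero = max(s.col_exit for s in g.seps) + tg.FIB_DROP_CELLS
            assert not np.any(g.type_map[:, col_zero:] == tg.FIBROBLAST)
            # outside pathway row bands the atrium is clean everywhere
            band = np.zeros(g.nrows, dtype=bool)
            for s in g.seps:
                band[s.row0:s.row1] = True
            right = g.type_map[~band, g.config.center[1] + 15:]
            assert not np.any(right == tg.FIBROBLAST)

    def test_binomial_consistency_of_central_counts(self, placed):
        # realised counts should be consistent with independent Bernoulli
        # placement at the configured plateau probability (chi-square, 5 %)
        g = placed[0]
        mask = g.san_region_mask()
        cfg = g.config
        plateau = cfg.center[1] + cfg.semi_minor - 2
        mask[:, plateau + 1:] = False
        n = int(mask.sum())
        k = int((g.type_map[mask] == tg.FIBROBLAST).sum())
        p = 0.457
        chi2 = (k - n * p) ** 2 / (n * p * (1 - p))
        assert chi2 < stats.chi2.ppf(0.95, df=1)

    def test_degenerate_zero_density_unchanged(self):
        geom = tg.build_geometry(tg.full_preset())
        out = tg.place_fibroblasts(geom, seed=1, p_central=0.0)
        assert np.array_equal(out.type_map, geom.type_map)


class TestHeterogeneity:
    def test_lognormal_width(self):
        geom = tg.build_geometry(tg.full_preset())
        het = tg.sample_heterogeneity(geom, seed=7, sigma=0.2)
        logs = np.log(het.multipliers.ravel())
        assert het.multipliers.shape[1] == 11
        assert logs.std() == pytest.approx(0.2, abs=0.01)
        assert np.median(het.multipliers) == pytest.approx(1.0, abs=0.01)
        assert np.all(het.multipliers > 0)

    def test_same_seed_bitwise_identical(self):
        geom = tg.build_geometry(tg.full_preset())
        a = tg.sample_heterogeneity(geom, seed=11)
        b = tg.sample_heterogeneity(geom, seed=11)
        assert np.array_equal(a.multipliers, b.multipliers)
        c = tg.sample_heterogeneity(geom, seed=12)
        assert not np.array_equal(a.multipliers, c.multipliers)

    def test_small_sigma_approaches_uniform(self):
        geom = tg.build_geometry(tg.strip_preset())
        het = tg.sample_heterogeneity(geom, seed=1, sigma=1e-9)
        np.testing.assert_allclose(het.multipliers, 1.0, atol=1e-7)

    def test_nonpositive_sigma_rejected(self):
        geom = tg.build_geometry(tg.strip_preset())
        with pytest.raises(ValueError):
            tg.sample_heterogeneity(geom, seed=1, sigma=0.0)


class TestCoupling:
    def test_sigmoid_profile_limits_and_midpoint(self):
        # deep SAN -> 1e-3 uS at 1 GOhm; atrial far field -> 1 uS at 1 MOhm;
        # the midpoint of the profile is the average of the two levels
        assert tg.sigmoid_profile(1e3, 1000.0, 1.0, 1.0, 37.0) == \
            pytest.approx(1e-3, rel=1e-6)
        assert tg.sigmoid_profile(-1e3, 1000.0, 1.0, 1.0, 37.0) == \
            pytest.approx(1.0, rel=1e-6)
        mid = tg.sigmoid_profile(37.0, 1000.0, 1.0, 1.0, 37.0)
        assert mid == pytest.approx((1.0 + 1e-3) / 2, rel=1e-9)

    def test_cell_conductances_by_type(self):
        geom = tg.build_geometry(tg.full_preset())
        geom = tg.place_fibroblasts(geom, seed=1)
        cmap = tg.build_coupling(geom)
        g = cmap.g_cell
        tm = geom.type_map
        assert np.all(g[tm == tg.INSULATOR] == 0.0)
        assert np.all(g[tm == tg.FIBROBLAST] == pytest.approx(1e-3))
        # atrial far field (left border) at 1/R_RA
        assert g[5, 5] == pytest.approx(1.0)
        # deep SAN at 1/R_SAN
        cr, cc = geom.config.center
        assert g[cr, cc] == pytest.approx(1e-3, rel=1e-3)

    def test_profile_monotone_along_pathway(self):
        geom = tg.build_geometry(tg.full_preset())
        cmap = tg.build_coupling(geom)
        s = geom.seps[2]  # central pathway
        prof = cmap.g_cell[s.center_row, s.col_start - 5:s.col_exit + 15]
        assert np.all(np.diff(prof) >= -1e-12)

    def test_nonpositive_resistance_rejected(self):
        geom = tg.build_geometry(tg.strip_preset())
        with pytest.raises(ValueError):
            tg.build_coupling(geom, tg.CouplingConfig(R_RA=0.0))


class TestSetupFactory:
    def test_four_setups(self):
        cfg = tg.strip_preset()
        u, h_u = tg.build_setup("U", 1, cfg)
        h, h_h = tg.build_setup("H", 1, cfg)
        uf, h_uf = tg.build_setup("UF", 1, cfg)
        hf, h_hf = tg.build_setup("HF", 1, cfg)
        assert h_u is None and h_uf is None
        assert h_h is not None and h_hf is not None
        assert not np.any(u.type_map == tg.FIBROBLAST)
        assert not np.any(h.type_map == tg.FIBROBLAST)
        assert np.any(uf.type_map == tg.FIBROBLAST)
        assert np.any(hf.type_map == tg.FIBROBLAST)

    def test_unknown_setup_rejected(self):
        with pytest.raises(ValueError):
            tg.build_setup("X", 1)


class TestSerialization:
    def test_roundtrip(self, tmp_path):
        geom = tg.build_geometry(tg.strip_preset())
        cmap = tg.build_coupling(geom)
        path = tmp_path / "geom.h5"
        tg.save_geometry(path, geom, cmap)
        g2, c2 = tg.load_geometry(path)
        assert np.array_equal(g2.type_map, geom.type_map)
        assert g2.config == geom.config
        np.testing.assert_allclose(c2.g_cell, cmap.g_cell)
        assert [s.sep_id for s in g2.seps] == [s.sep_id for s in geom.seps]
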