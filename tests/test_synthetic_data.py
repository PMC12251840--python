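import numpy as np
import pytest
from scipy.stats import chisquare

from climascreen.climate_raster import extract_at_points, link_climate
from climascreen.niche_profile import build_profiles
from climascreen.synthetic_data import (
    SurfaceConfig,
    VirtualSpecies,
    default_surface_config,
    gen_climate_grid,
    gen_dataset,
    gen_occurrences,
    gen_species_pool,
    read_manifest,
    suitability_weights,
    write_manifest,
)


class TestClimateGrid:
    def test_deterministic_under_seed(self):
        cfg = default_surface_config("PDQ", seed=11)
        a = gen_climate_grid(cfg, "PDQ")
        b = gen_climate_grid(cfg, "PDQ")
        np.testing.assert_array_equal(a.values, b.values)

    def test_zero_noise_is_exact_gradient_formula(self):
        cfg = SurfaceConfig(base=100.0, gradient=-2.5, noise_amp=0.0)
        grid = gen_climate_grid(cfg, "PDQ")
        expected = np.broadcast_to(
            (100.0 - 2.5 * grid.cell_center_lats())[:, None], grid.values.shape
        )
        np.testing.assert_allclose(grid.values, expected, rtol=1e-12)

    def test_zero_nodata_fraction_means_no_gaps(self):
        grid = gen_climate_grid(default_surface_config("MTCM", seed=1), "MTCM")
        assert not np.isnan(grid.values).any()

    def test_declared_nodata_fraction_applied(self):
        cfg = default_surface_config("PDQ", seed=2, nodata_fraction=0.1)
        grid = gen_climate_grid(cfg, "PDQ")
        n = grid.values.size
        assert np.isnan(grid.values).sum() == round(0.1 * n)

    def test_degenerate_configs_rejected(self):
        with pytest.raises(ValueError):
            SurfaceConfig(lat_min=30, lat_max=30)
        with pytest.raises(ValueError):
            SurfaceConfig(cell_size=0)
        with pytest.raises(ValueError):
            SurfaceConfig(nodata_fraction=1.5)


class TestSpeciesPool:
    @pytest.fixture()
    def grids(self):
        pdq = gen_climate_grid(default_surface_config("PDQ", seed=3), "PDQ")
        mtcm = gen_climate_grid(default_surface_config("MTCM", seed=3), "MTCM")
        return pdq, mtcm

    def test_exact_planted_counts_below_landscape_q25(self, grids):
        pdq, mtcm = grids
        pool = gen_species_pool(35, 9, 9, pdq, mtcm, seed=4)
        q25_p = np.quantile(pdq.values[~np.isnan(pdq.values)], 0.25)
        q25_t = np.quantile(mtcm.values[~np.isnan(mtcm.values)], 0.25)
        assert sum(sp.planted_drought for sp in pool) == 9
        assert sum(sp.planted_cold for sp in pool) == 9
        assert sum(sp.mu_pdq < q25_p for sp in pool) == 9
        assert sum(sp.mu_mtcm < q25_t for sp in pool) == 9

    def test_zero_planted_and_determinism(self, grids):
        pool = gen_species_pool(10, 0, 0, *grids, seed=5)
        assert not any(sp.planted_drought or sp.planted_cold for sp in pool)
        assert pool == gen_species_pool(10, 0, 0, *grids, seed=5)

    def test_planted_counts_exceeding_pool_rejected(self, grids):
        with pytest.raises(ValueError):
            gen_species_pool(10, 6, 5, *grids, seed=0)

    def test_uneven_sampling_by_default(self, grids):
        pool = gen_species_pool(30, 0, 0, *grids, seed=6)
        counts = {sp.n_occurrences for sp in pool}
        assert len(counts) > 3 and min(counts) >= 10

    def test_manifest_round_trip(self, grids, tmp_path):
        pool = gen_species_pool(5, 1, 1, *grids, seed=7)
        write_manifest(pool, tmp_path / "m.json")
        assert read_manifest(tmp_path / "m.json") == pool


def toy_five_cell_grids():
    """A 1x5 landscape with hand-set climate values for enumeration oracles."""
    from conftest import make_grid

    pdq = make_grid([[30.0, 50.0, 70.0, 90.0, 110.0]], "PDQ")
    mtcm = make_grid([[0.0, 1.0, 2.0, 3.0, 4.0]], "MTCM")
    return pdq, mtcm


class TestOccurrences:
    def test_exact_count_inside_extent_on_valid_cells(self):
        ds = gen_dataset(n_species=3, n_planted_drought=1, n_planted_cold=1,
                         seed=8, n_occurrences=30)
        for sp in ds.pool:
            occ = [r for r in ds.occurrences if r.species == sp.name]
            assert len(occ) == 30
            lats = [r.lat for r in occ]
            lons = [r.lon for r in occ]
            assert min(lats) >= ds.pdq_grid.y_ll and max(lats) < ds.pdq_grid.y_ur
            assert min(lons) >= ds.pdq_grid.x_ll and max(lons) < ds.pdq_grid.x_ur
            assert not np.isnan(extract_at_points(ds.pdq_grid, lats, lons)).any()

    def test_narrow_niche_concentrates_on_single_matching_cell(self):
        pdq, mtcm = toy_five_cell_grids()
        sp = VirtualSpecies("sp", mu_pdq=70.0, mu_mtcm=2.0, sigma_pdq=0.5,
                            sigma_mtcm=0.05, planted_drought=False,
                            planted_cold=False, n_occurrences=50)
        occ = gen_occurrences(sp, pdq, mtcm, seed=9)
        values = extract_at_points(pdq, [r.lat for r in occ], [r.lon for r in occ])
        assert (values == 70.0).all()

    def test_niche_outside_landscape_range_raises(self):
        pdq, mtcm = toy_five_cell_grids()
        sp = VirtualSpecies("sp", mu_pdq=10_000.0, mu_mtcm=500.0, sigma_pdq=1.0,
                            sigma_mtcm=1.0, planted_drought=False,
                            planted_cold=False, n_occurrences=5)
        with pytest.raises(ValueError, match="outside"):
            gen_occurrences(sp, pdq, mtcm, seed=0)

    def test_mean_extracted_pdq_matches_discrete_mixture_oracle(self):
        """The suitability-weighted cell-value distribution is fully enumerable
        on the 5-cell landscape; the sample mean of 10,000 extracted PDQ
        values must sit within Monte-Carlo error of the exact mixture mean."""
        pdq, mtcm = toy_five_cell_grids()
        sp = VirtualSpecies("sp", mu_pdq=60.0, mu_mtcm=1.5, sigma_pdq=25.0,
                            sigma_mtcm=2.0, planted_drought=False,
                            planted_cold=False, n_occurrences=10_000)
        w = suitability_weights(sp, pdq.values[0], mtcm.values[0])
        probs = w / w.sum()
        exact_mean = probs @ pdq.values[0]
        exact_sd = np.sqrt(probs @ (pdq.values[0] - exact_mean) ** 2)
        occ = gen_occurrences(sp, pdq, mtcm, seed=10)
        values = extract_at_points(pdq, [r.lat for r in occ], [r.lon for r in occ])
        assert values.mean() == pytest.approx(exact_mean, abs=4 * exact_sd / 100)

    def test_cell_counts_fit_suitability_distribution(self):
        """Chi-squared goodness of fit of sampled cell frequencies against the
        exact suitability weights on the 5-cell toy landscape (alpha=0.01)."""
        pdq, mtcm = toy_five_cell_grids()
        sp = VirtualSpecies("sp", mu_pdq=70.0, mu_mtcm=2.0, sigma_pdq=30.0,
                            sigma_mtcm=2.5, planted_drought=False,
                            planted_cold=False, n_occurrences=4000)
        w = suitability_weights(sp, pdq.values[0], mtcm.values[0])
        probs = w / w.sum()
        occ = gen_occurrences(sp, pdq, mtcm, seed=12)
        values = extract_at_points(pdq, [r.lat for r in occ], [r.lon for r in occ])
        observed = np.array([(values == v).sum() for v in pdq.values[0]])
        stat, p = chisquare(observed, f_exp=probs * 4000)
        assert p > 0.01


def test_planted_species_have_lower_medians_across_replicate_pools():
    """Over 20 independent pools, planted species must show systematically
    drier / colder realized medians than the background pool."""
    diffs_p, diffs_t = [], []
    for seed in range(20):
        ds = gen_dataset(n_species=12, n_planted_drought=3, n_planted_cold=3,
                         seed=seed, n_occurrences=15)
        linked, _ = link_climate(ds.occurrences, ds.pdq_grid, ds.mtcm_grid)
        profiles = {p.species: p for p in build_profiles(linked)}
        planted_d = [profiles[s.name].median_pdq for s in ds.pool if s.planted_drought]
        other_d = [profiles[s.name].median_pdq for s in ds.pool if not s.planted_drought]
        planted_c = [profiles[s.name].median_mtcm for s in ds.pool if s.planted_cold]
        other_c = [profiles[s.name].median_mtcm for s in ds.pool if not s.planted_cold]
        diffs_p.append(np.median(other_d) - np.median(planted_d))
        diffs_t.append(np.median(other_c) - np.median(planted_c))
    assert np.mean(diffs_p) > 0 and np.mean(diffs_t) > 0
    assert np.mean([d > 0 for d in diffs_p]) >= 0.9
    assert np.mean([d > 0 for d in diffs_t]) >= 0.9
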