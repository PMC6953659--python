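import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.stats import multivariate_normal

import surveygap as sg
from surveygap.simulate import make_powerlaw_species

from conftest import moran_i


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"guild_mix": (0.5, 0.5, 0.5)},
            {"n_ecoregions": 1},
            {"guild_detect": (0.0, 0.5, 1.0)},
            {"grid_rows": 2, "grid_cols": 2},
            {"n_species": 2},
            {"tau_true": -1.0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            sg.SimConfig(**kwargs)


class TestLandscape:
    def test_two_by_two_two_ecoregions(self):
        # smallest legal grid: both ecoregion labels present, every cell labeled
        cfg = sg.SimConfig(grid_rows=4, grid_cols=4, n_ecoregions=2, seed=0)
        grid, cells, _ = sg.make_landscape(cfg)
        eco = grid.cells["ecoregion"]
        assert set(eco.unique()) == {0, 1}
        assert eco.notna().all()

    def test_ecoregions_contiguous(self):
        cfg = sg.SimConfig(grid_rows=12, grid_cols=12, n_ecoregions=5, seed=3)
        grid, _, _ = sg.make_landscape(cfg)
        eco = grid.cells["ecoregion"].to_numpy()
        for label in range(5):
            ids = np.flatnonzero(eco == label)
            sub = sg.build_adjacency(grid, subset=ids, rule="rook")
            assert sub.n_components == 1

    def test_determinism_under_fixed_seed(self):
        cfg = sg.SimConfig(grid_rows=20, grid_cols=20, seed=9)
        _, cells1, _ = sg.make_landscape(cfg)
        _, cells2, _ = sg.make_landscape(cfg)
        pd.testing.assert_frame_equal(cells1, cells2)

    def test_covariates_spatially_autocorrelated(self):
        """Moran's I of every covariate over queen adjacency is positive,
        against a direct brute-force Moran's I computation."""
        cfg = sg.SimConfig(grid_rows=30, grid_cols=30, seed=5)
        grid, cells, _ = sg.make_landscape(cfg)
        graph = sg.lattice_adjacency(30, 30)
        for name in [c for c in cells.columns if not c.startswith("z_")]:
            assert moran_i(cells[name].to_numpy(), graph) > 0.2, name


class TestSpeciesPool:
    def test_degenerate_guild_mix(self):
        cfg = sg.SimConfig(grid_rows=5, grid_cols=5, n_species=3, guild_mix=(1.0, 0.0, 0.0), seed=1)
        grid, _, _ = sg.make_landscape(cfg)
        species, _ = sg.make_species_pool(cfg, grid)
        assert (species["guild"] == "open").all()

    def test_range_cells_match_emitted_sets(self, small_dataset):
        species = small_dataset["species"]
        ranges = small_dataset["ranges"]
        for name, row in species.iterrows():
            assert row["range_cells"] == len(ranges[name])
            assert len(set(ranges[name])) == len(ranges[name])

    def test_ranges_connected(self, small_dataset):
        grid = small_dataset["grid"]
        for name, cells in small_dataset["ranges"].items():
            sub = sg.build_adjacency(grid, subset=cells)
            assert sub.n_components == 1, name

    def test_log_range_sizes_approximately_uniform(self):
        cfg = sg.SimConfig(grid_rows=30, grid_cols=30, n_species=500, seed=11)
        grid, _, _ = sg.make_landscape(cfg)
        species, _ = sg.make_species_pool(cfg, grid)
        logs = np.log(species["range_cells"].to_numpy(float))
        hist, edges = np.histogram(logs, bins=10, range=(0.0, np.log(900)))
        chi2, p = stats.chisquare(hist)
        assert p > 0.01


class TestRecords:
    def test_zero_detection_zero_records(self):
        cfg = sg.SimConfig(
            grid_rows=8, grid_cols=8, n_species=5, guild_detect=(1e-12, 1e-12, 1e-12), seed=2
        )
        d = sg.simulate_dataset(cfg)
        assert len(d["records"]) == 0

    def test_records_inside_generating_range(self, small_dataset):
        grid = small_dataset["grid"]
        recs = small_dataset["records"]
        truth = small_dataset["truth"]
        ids = grid.locate(recs["lon"].to_numpy(), recs["lat"].to_numpy())
        for sp, cid in zip(recs["species"], ids):
            assert cid in truth.ranges[sp]

    def test_byte_identical_outputs_fixed_seed(self):
        cfg = sg.SimConfig(grid_rows=10, grid_cols=10, n_species=20, seed=4)
        d1 = sg.simulate_dataset(cfg)
        d2 = sg.simulate_dataset(cfg)
        pd.testing.assert_frame_equal(d1["records"], d2["records"])
        assert (d1["truth"].phi == d2["truth"].phi).all()

    def test_homogeneous_limit_is_poisson(self):
        """beta=0, tau huge (phi ~ 0): per-cell totals are Poisson — the
        dispersion index over 50 replicates has a CI covering 1."""
        cfg = sg.SimConfig(
            grid_rows=8,
            grid_cols=8,
            n_species=3,
            beta_true=(0.0,) * 7,
            tau_true=1e8,
            alpha_true=0.0,
            guild_detect=(1.0, 1.0, 1.0),
            seed=6,
        )
        grid, cells, _ = sg.make_landscape(cfg)
        species, ranges = sg.make_species_pool(cfg, grid)
        full = np.arange(grid.n_cells)
        ranges = {k: full for k in ranges}  # whole-grid ranges: identical rate
        species["range_cells"] = grid.n_cells
        idx = []
        for rep in range(50):
            cfg_rep = sg.SimConfig(**{**cfg.__dict__, "seed": 600 + rep})
            recs, _ = sg.simulate_records(grid, cells, species, ranges, cfg_rep)
            counts = np.bincount(
                grid.locate(recs["lon"].to_numpy(), recs["lat"].to_numpy()),
                minlength=grid.n_cells,
            )
            idx.append(counts.var(ddof=1) / counts.mean())
        mean_idx = np.mean(idx)
        se = np.std(idx, ddof=1) / np.sqrt(len(idx))
        assert mean_idx - 3 * se < 1.0 < mean_idx + 3 * se

    def test_mismatched_cells_rejected(self, small_dataset):
        cfg = sg.SimConfig(grid_rows=20, grid_cols=20, n_species=60, seed=42)
        with pytest.raises(ValueError, match="align"):
            sg.simulate_records(
                small_dataset["grid"],
                small_dataset["cells"].iloc[:10],
                small_dataset["species"],
                small_dataset["ranges"],
                cfg,
            )


class TestICARPrior:
    def test_phi_sums_to_zero(self, small_dataset):
        assert abs(small_dataset["truth"].phi.sum()) < 1e-8

    @pytest.mark.parametrize("shape", [(2, 2), (5, 5)])
    def test_logpdf_matches_bruteforce_quadform(self, shape):
        """Module log-density == -(tau/2) sum over neighbor pairs of
        (phi_i - phi_j)^2, enumerated directly."""
        g = sg.lattice_adjacency(*shape)
        rng = np.random.default_rng(0)
        tau = 2.5
        phi = sg.sample_icar(g, tau, rng)
        brute = 0.0
        n_cols = shape[1]
        for i in range(g.n):
            for j in range(i + 1, g.n):
                ri, ci = divmod(i, n_cols)
                rj, cj = divmod(j, n_cols)
                if max(abs(ri - rj), abs(ci - cj)) == 1:
                    brute += (phi[i] - phi[j]) ** 2
        assert sg.icar_logpdf(phi, g, tau, normalized=False) == pytest.approx(
            -tau / 2 * brute, abs=1e-10
        )

    def test_logpdf_matches_generalized_inverse_density(self):
        """Normalized density equals a dense degenerate-Gaussian evaluation
        via the Laplacian pseudo-inverse on a 6-node graph."""
        g = sg.lattice_adjacency(2, 3)
        rng = np.random.default_rng(1)
        tau = 1.7
        for _ in range(5):
            phi = sg.sample_icar(g, tau, rng)
            dense = multivariate_normal(
                mean=np.zeros(6), cov=np.linalg.pinv(tau * g.laplacian()), allow_singular=True
            ).logpdf(phi)
            assert sg.icar_logpdf(phi, g, tau) == pytest.approx(dense, abs=1e-8)

    def test_sample_variance_matches_spectrum(self):
        """Empirical variance of smooth-mode coefficients matches 1/(tau
        lambda) from the Laplacian spectrum."""
        g = sg.lattice_adjacency(4, 4)
        lam, V = np.linalg.eigh(g.laplacian())
        rng = np.random.default_rng(2)
        tau = 3.0
        draws = np.array([sg.sample_icar(g, tau, rng) for _ in range(4000)])
        c = draws @ V[:, 1]  # smoothest non-null mode
        assert c.var() == pytest.approx(1.0 / (tau * lam[1]), rel=0.1)


class TestPowerlawSpeciesGenerator:
    def test_noise_free_exact_relation(self):
        sp = make_powerlaw_species(sigma=0.0, amplitude=2.0, b=(0.7, 0.7, 0.7), seed=0)
        assert np.allclose(sp["sampled_cells"], 2.0 * sp["range_cells"] ** 0.7)

    def test_b_target_expectation(self):
        """Calibrated-detectability mode: mean sampled cells tracks
        a * range^b per guild."""
        cfg = sg.SimConfig(
            grid_rows=25, grid_cols=25, n_species=300, b_target=(0.6, 0.6, 0.6),
            b_amplitude=1.0, seed=8,
        )
        d = sg.simulate_dataset(cfg)
        sc = sg.species_sampled_cells(d["records"], d["grid"])
        sp = d["species"].join(sc).fillna({"sampled_cells": 0})
        big = sp[sp["range_cells"] >= 50]
        ratio = big["sampled_cells"] / big["range_cells"] ** 0.6
        assert ratio.mean() == pytest.approx(1.0, abs=0.05)
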