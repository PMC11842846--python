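"""Lineage simulator and monolayer generator."""

import numpy as np
import pandas as pd
import pytest

from epimorph import (LineageParams, MarkParams, MonolayerParams,
                      dilution_osmolarity, generate_monolayer,
                      lineage_to_population, simulate_lineage)
from epimorph.synthetic import EmptyTimepointError

from _oracles import multiplicative_division_paths, pearson_by_summation


class TestLineage:
    def test_symmetric_split_halves_mother_area(self):
        params = LineageParams(division_asymmetry_sd=0.0, generations=2,
                               n_initial=1, growth_rate=0.0, seed=0)
        tab = simulate_lineage(params)
        gen1 = tab[(tab.generation == 1) & (tab.time_h == 6)]
        assert np.allclose(gen1.cell_area, params.initial_area / 2)

    def test_no_growth_keeps_area_constant_over_six_hours(self):
        tab = simulate_lineage(LineageParams(growth_rate=0.0, generations=2,
                                             n_initial=2, seed=3))
        for _, grp in tab.groupby("cell_id"):
            assert np.allclose(grp.cell_area, grp.cell_area.iloc[0])

    def test_area_conserved_at_every_division(self):
        tab = simulate_lineage(LineageParams(generations=4, n_initial=2,
                                             seed=5))
        end = tab.sort_values("time_h").groupby("cell_id").last()
        daughters = tab[tab.parent_id >= 0].groupby("cell_id").first()
        summed = daughters.groupby("parent_id").cell_area.sum()
        mothers = end.loc[summed.index, "cell_area"]
        assert np.allclose(summed.to_numpy(), mothers.to_numpy(), rtol=1e-12)

    def test_every_nonroot_has_one_parent_and_time_nondecreasing(self):
        tab = simulate_lineage(LineageParams(generations=3, n_initial=1,
                                             seed=9))
        parents = tab[tab.parent_id >= 0].groupby("cell_id").parent_id.nunique()
        assert (parents == 1).all()
        for _, grp in tab.groupby("cell_id"):
            assert grp.time_h.is_monotonic_increasing
        assert set(tab[tab.parent_id >= 0].parent_id) <= set(tab.cell_id)

    def test_log_area_variance_grows_linearly_matching_resampling_oracle(self):
        """Var(ln area) at birth vs generation: slope within 5% of an
        independent truncated-normal resampling of the same process.

        Shared ancestry makes a single tree's variance curve noisy even with
        ~10^4 terminal cells, so the curve is averaged over several seeded
        trees before fitting the slope."""
        gens = np.arange(13)
        curves = []
        for seed in range(10):
            params = LineageParams(division_asymmetry_sd=0.1, generations=12,
                                   n_initial=3, growth_rate=0.0,
                                   growth_hours=1, seed=21 + seed)
            tab = simulate_lineage(params)
            births = tab[tab.time_h == tab.generation * params.growth_hours]
            curves.append([
                np.log(births[births.generation == g].cell_area).var()
                for g in gens])
        var_sim = np.mean(curves, axis=0)
        slope_sim = np.polyfit(gens, var_sim, 1)[0]
        lnA = multiplicative_division_paths(20_000, params.generations,
                                            sd=0.1, seed=77)
        var_mc = lnA.var(axis=0)
        slope_mc = np.polyfit(gens, var_mc, 1)[0]
        assert slope_sim == pytest.approx(slope_mc, rel=0.05)

    def test_terminal_population_is_lognormal_with_reported_width(self):
        """Default simulation: mean-normalised terminal areas carry
        2*Var(ln x) within 0.05 of the observed 0.19."""
        tab = simulate_lineage(LineageParams(seed=1))
        t_end = tab.time_h.max()
        areas, _ = lineage_to_population(tab, t_end)
        x = areas / areas.mean()
        assert 2 * np.log(x).var() == pytest.approx(0.19, abs=0.05)

    def test_lognormality_emerges_over_many_generations(self):
        """>=10 multiplicative divisions: independent terminal leaves pass a
        KS test against the fitted log-normal (20 seeds averaged)."""
        from epimorph import fit_lognormal

        pvals = []
        for seed in range(20):
            params = LineageParams(division_asymmetry_sd=0.1, generations=10,
                                   n_initial=30, growth_rate=0.0,
                                   growth_hours=1, seed=seed)
            tab = simulate_lineage(params)
            term = tab[(tab.generation == 10)
                       & (tab.time_h == 10 * params.growth_hours)]
            # sparse random thinning of ~30k leaves: near-independent sample
            rng = np.random.default_rng(seed)
            leaves = term.cell_id.to_numpy()
            pick = rng.choice(leaves, size=100, replace=False)
            x = term[term.cell_id.isin(pick)].cell_area.to_numpy()
            x = x / x.mean()
            pvals.append(fit_lognormal(x).ks_p)
        assert np.mean(pvals) > 0.05

    def test_population_query_pairs_and_empty_signal(self):
        params = LineageParams(generations=1, n_initial=2, seed=2)
        tab = simulate_lineage(params)
        cell, nuc = lineage_to_population(tab, 0.0)
        assert cell.shape == nuc.shape == (2,)
        with pytest.raises(EmptyTimepointError):
            lineage_to_population(tab, 999.0)

    def test_zero_nc_noise_gives_perfect_area_coupling(self):
        tab = simulate_lineage(LineageParams(nc_noise_sd=0.0, generations=3,
                                             n_initial=4, seed=4))
        cell, nuc = lineage_to_population(tab, tab.time_h.max())
        assert pearson_by_summation(cell, nuc) == pytest.approx(1.0, abs=1e-12)

    def test_seed_determinism_bit_identical(self):
        p = LineageParams(generations=4, n_initial=2, seed=11)
        assert simulate_lineage(p).equals(simulate_lineage(p))

    @pytest.mark.parametrize("bad", [
        dict(initial_area=0.0), dict(initial_area=np.nan),
        dict(division_asymmetry_sd=0.3), dict(growth_rate=-0.1),
        dict(nc_ratio=1.5), dict(generations=0),
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            simulate_lineage(LineageParams(**bad))


class TestOsmolarity:
    def test_hypotonic_shock_dilution(self):
        assert dilution_osmolarity(290, 0.05) == pytest.approx(14.5)

    def test_identity_and_linearity(self):
        assert dilution_osmolarity(123.4, 1.0) == 123.4
        assert dilution_osmolarity(300, 0.5) == 150.0

    def test_fraction_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            dilution_osmolarity(290, 1.2)
        with pytest.raises(ValueError):
            dilution_osmolarity(np.inf, 0.5)


class TestMonolayer:
    def test_nuclei_inside_their_cells_and_labels_partition_field(
            self, small_monolayer):
        m = small_monolayer
        nuc = m.nucleus_labels > 0
        assert (m.nucleus_labels[nuc] == m.cell_labels[nuc]).all()
        assert (m.cell_labels > 0).all()  # tessellation covers the field
        ids = np.unique(m.cell_labels)
        assert ids.min() >= 1 and np.unique(ids).size == ids.size

    def test_seed_determinism_bit_identical(self):
        p = MonolayerParams(n_cells=60, field_size=256, seed=13)
        a = generate_monolayer(p)
        b = generate_monolayer(p)
        assert np.array_equal(a.cell_labels, b.cell_labels)
        assert np.array_equal(a.nucleus_labels, b.nucleus_labels)
        for name in a.channels:
            assert np.array_equal(a.channels[name], b.channels[name])

    def test_rendered_mark_levels_match_sampled_truth(self, clean_monolayer):
        """Mask-free oracle: per-nucleus mark/DAPI measured from the images
        agrees with the sampled ground-truth levels (r > 0.99, no noise)."""
        from scipy import ndimage

        m = clean_monolayer
        truth = m.truth.set_index("label_id")
        ids = truth.index.to_numpy()
        mark = ndimage.mean(m.channels["H3K27me3"], m.nucleus_labels, ids)
        dapi = ndimage.mean(m.channels["DAPI"], m.nucleus_labels, ids)
        measured = mark / dapi
        r = pearson_by_summation(measured, truth["H3K27me3_level"].to_numpy())
        assert r > 0.99

    @pytest.mark.parametrize("slope", [-0.3, 0.3])
    def test_mark_size_coupling_sign(self, slope):
        """Negative slope (H3K27me3-like) gives anti-correlation of
        mark/DAPI with nucleus area; positive slope flips the sign."""
        from scipy import ndimage, stats

        params = MonolayerParams(
            n_cells=300, field_size=640, seed=int(10 * abs(slope)) + 3,
            marks={"MARK": MarkParams(slope=slope, noise_sd=0.05)})
        m = generate_monolayer(params)
        ids = m.truth["label_id"].to_numpy()
        mark = ndimage.mean(m.channels["MARK"], m.nucleus_labels, ids)
        dapi = ndimage.mean(m.channels["DAPI"], m.nucleus_labels, ids)
        area = ndimage.sum_labels(m.nucleus_labels > 0, m.nucleus_labels, ids)
        res = stats.pearsonr(area, mark / dapi)
        assert np.sign(res.statistic) == np.sign(slope)
        assert res.pvalue < 0.01
        # magnitude against the mask-free oracle from sampled levels
        r_oracle = stats.pearsonr(m.truth["nucleus_area_px"],
                                  m.truth["MARK_level"]).statistic
        assert res.statistic == pytest.approx(r_oracle, abs=0.1)

    def test_uniform_nucleus_intensity_when_gradient_off(self, clean_monolayer):
        """radial_coupling=0 and no pixel noise: every nucleus is uniform, so
        periphery/centre ratio is 1 within 2%."""
        from epimorph import radial_stat

        tab = radial_stat(clean_monolayer, "H3K27me3")
        assert len(tab) > 30
        assert np.allclose(tab.periphery_center_ratio, 1.0, atol=0.02)

    def test_infeasible_geometry_counts_clipped_nuclei(self):
        params = MonolayerParams(n_cells=60, field_size=256, nc_ratio=0.95,
                                 nc_noise_sd=0.5, seed=8)
        m = generate_monolayer(params)
        assert m.n_clipped_nuclei > 0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            MonolayerParams(n_cells=2).validate()
        with pytest.raises(ValueError):
            MonolayerParams(nc_ratio=0.0).validate()
        with pytest.raises(ValueError):
            MonolayerParams(ar_gamma_k=-1.0).validate()
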