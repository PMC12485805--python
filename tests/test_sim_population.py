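"""Population simulation: baselines, caQTL assignment/effects, pseudobulk."""

import numpy as np
import pandas as pd
import pytest

from picsim import (
    CVBin,
    LibSizeParams,
    PopulationParams,
    SparsityParams,
    aggregate_pseudobulk,
    apply_condition_da,
    apply_genotype_effects,
    assign_caqtl_effects,
    sample_population_baselines,
    simulate_population,
)
from picsim.fixtures import generate_genotype_fixture, generate_peak_fixture
from picsim.sim_population import CaQTLAssignment, GenotypeTable, IndividualBaselines


def _pop(**kw):
    defaults = dict(
        cv_bins=[CVBin(lo=0.0, hi=1e9, alpha_v=2.0, beta_v=10.0)],
        ca_maf_range=(0.05, 0.5),
    )
    defaults.update(kw)
    return PopulationParams(**defaults)


@pytest.fixture(scope="module")
def geno():
    return generate_genotype_fixture(20, 800, chrom_length=5_000_000, seed=5)


@pytest.fixture(scope="module")
def peaks():
    return generate_peak_fixture(200, chrom_length=5_000_000, seed=5)


class TestBaselines:
    def test_var_scale_zero_copies_population_mean(self, rng):
        base = sample_population_baselines(_pop(var_scale=0.0), 50, ["a", "b", "c"], rng)
        for ind in "abc":
            np.testing.assert_allclose(base.baselines[ind].to_numpy(), base.lam)

    def test_across_individual_cv_matches_bin_law(self, rng):
        pop = _pop(var_scale=1.0)
        inds = [f"i{k}" for k in range(200)]
        base = sample_population_baselines(pop, 300, inds, rng)
        mat = base.baselines.to_numpy()
        est_sd = mat.std(axis=1, ddof=1)
        ok = base.lam > np.quantile(base.lam, 0.3)  # avoid clamp-distorted peaks
        rel = est_sd[ok] / base.sigma[ok]
        assert np.median(np.abs(rel - 1)) < 0.15

    def test_empirical_bypass_pass_through(self, rng):
        means = np.array([1.0, 5.0, 9.0])
        base = sample_population_baselines(
            _pop(), 3, ["x", "y"], rng, empirical_means=means
        )
        np.testing.assert_allclose(base.baselines["x"], means)
        np.testing.assert_allclose(base.baselines["y"], means)


class TestAssignCaQTL:
    def test_abundant_snps_exact_count(self, rng, geno, peaks):
        big_geno = generate_genotype_fixture(20, 4000, chrom_length=5_000_000, seed=6)
        big_peaks = generate_peak_fixture(1000, chrom_length=5_000_000, seed=6)
        a = assign_caqtl_effects(big_peaks, big_geno, _pop(ca_peaks=0.7), rng)
        assert len(a) == 700
        assert len({x.peak_id for x in a}) == 700

    def test_ca_peaks_zero_empty(self, rng, geno, peaks):
        assert assign_caqtl_effects(peaks, geno, _pop(ca_peaks=0.0), rng) == []

    def test_window_and_maf_constraints_respected(self, rng, geno, peaks):
        pop = _pop(ca_peaks=0.5, ca_window=20_000)
        a = assign_caqtl_effects(peaks, geno, pop, rng)
        maf_by_id = dict(zip(geno.snps["id"], geno.maf))
        for x in a:
            assert x.distance <= 20_000
            assert 0.05 <= maf_by_id[x.snp_id] <= 0.5

    def test_zero_window_selects_midpoint_snp(self, rng):
        peaks = pd.DataFrame(
            {"chrom": ["chr1"], "start": [101], "end": [200], "midpoint": [150]},
            index=pd.Index(["p1"], name="peak_id"),
        )
        snps = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "pos": [150, 500], "id": ["hit", "far"],
             "ref": ["A", "C"], "alt": ["G", "T"]}
        )
        geno = GenotypeTable(
            individuals=["i1", "i2"], snps=snps,
            dosages=np.array([[1, 0], [2, 1]]), maf=np.array([0.3, 0.2]),
        )
        a = assign_caqtl_effects(peaks, geno, _pop(ca_peaks=1.0, ca_window=1), rng)
        assert len(a) == 1 and a[0].snp_id == "hit"

    def test_no_eligible_snp_errors(self, rng, peaks):
        geno = generate_genotype_fixture(5, 3, chrom_length=5_000_000, seed=9)
        far = geno.snps.copy()
        far["pos"] = 4_999_990  # beyond any window used here
        bad = GenotypeTable(geno.individuals, far, geno.dosages, geno.maf)
        with pytest.raises(ValueError, match="eligible SNP"):
            assign_caqtl_effects(peaks.iloc[:3], bad, _pop(ca_peaks=1.0, ca_window=10), rng)


class TestApplyGenotypeEffects:
    def _base(self, value=10.0):
        df = pd.DataFrame(
            {"i1": [value], "i2": [value], "i3": [value]},
            index=pd.Index(["p1"], name="peak_id"),
        )
        return IndividualBaselines(df, lam=np.array([value]), sigma=np.zeros(1))

    def _geno(self, dosages):
        return GenotypeTable(
            individuals=["i1", "i2", "i3"],
            snps=pd.DataFrame({"chrom": ["c"], "pos": [1], "id": ["s"],
                               "ref": ["A"], "alt": ["G"]}),
            dosages=np.array(dosages)[:, None],
            maf=np.array([0.3]),
        )

    def test_dosage_linear_multiplier(self):
        out = apply_genotype_effects(
            self._base(), self._geno([0, 1, 2]),
            [CaQTLAssignment("p1", "s", 0.5, +1, 0)],
        )
        np.testing.assert_allclose(
            out.baselines.loc["p1"], [10.0, 12.5, 15.0]
        )  # x1, x1.25, x1.5

    def test_negative_effect_clamped_at_zero(self):
        out = apply_genotype_effects(
            self._base(), self._geno([0, 2, 2]),
            [CaQTLAssignment("p1", "s", 2.0, -1, 0)],
        )
        np.testing.assert_allclose(out.baselines.loc["p1"], [10.0, 0.0, 0.0])
        assert out.n_clamped == 2

    def test_unassigned_peaks_unchanged(self):
        base = self._base()
        out = apply_genotype_effects(base, self._geno([0, 0, 0]),
                                     [CaQTLAssignment("p1", "s", 0.9, +1, 0)])
        np.testing.assert_allclose(out.baselines.to_numpy(), base.baselines.to_numpy())


class TestConditionDA:
    def _base(self, n_peaks, inds):
        df = pd.DataFrame(
            np.full((n_peaks, len(inds)), 4.0),
            index=pd.Index([f"p{i}" for i in range(n_peaks)], name="peak_id"),
            columns=inds,
        )
        return IndividualBaselines(df, lam=np.full(n_peaks, 4.0), sigma=np.zeros(n_peaks))

    def test_single_cohort_noop(self, rng):
        base = self._base(30, ["a", "b"])
        out, table = apply_condition_da(base, {"a": "ctl", "b": "ctl"}, _pop(), rng)
        np.testing.assert_allclose(out.baselines.to_numpy(), 4.0)
        assert (table.to_numpy() == 1).all()

    def test_affected_fraction_binomial_bound(self, rng):
        pop = _pop()
        pop.da_condition.da_prob = 0.2
        base = self._base(5000, ["a", "b"])
        # sorted order makes "ctl" the reference; "dis" receives factors
        _, table = apply_condition_da(base, {"a": "ctl", "b": "dis"}, pop, rng)
        n_affected = int((table["dis"] != 1).sum())
        sd = np.sqrt(5000 * 0.2 * 0.8)
        assert abs(n_affected - 1000) < 3 * sd

    def test_all_negative_da_factors_below_one(self, rng):
        pop = _pop()
        pop.da_condition.down_prob = 1.0
        pop.da_condition.loc = 1.0
        pop.da_condition.scale = 0.1
        base = self._base(500, ["a", "b"])
        _, table = apply_condition_da(base, {"a": "ref", "b": "z"}, pop, rng)
        affected = table["z"][table["z"] != 1]
        assert len(affected) > 0 and (affected < 1).all()


class TestSimulatePopulation:
    def test_no_signal_gives_equal_pseudobulk(self):
        geno = generate_genotype_fixture(3, 50, chrom_length=1_000_000, seed=4)
        # identical genotypes across individuals
        geno.dosages[:] = geno.dosages[0][None, :]
        peaks = generate_peak_fixture(100, chrom_length=1_000_000, seed=4)
        pop = _pop(ca_peaks=0.0, var_scale=0.0)
        sim, truth = simulate_population(
            pop, geno, peaks, cells_per_individual=60,
            lib=LibSizeParams(7.0, 0.0), sparsity=SparsityParams(np.array([0.0])),
            seed=12,
        )
        pb = aggregate_pseudobulk(sim, normalize_cells=False)
        m = pb.to_numpy()
        keep = m.mean(axis=1) > 1
        rel_spread = m[keep].std(axis=1) / m[keep].mean(axis=1)
        # Poisson error of a 60-cell mean: cv ~ 1/sqrt(60*mean)
        assert np.median(rel_spread) < 3 / np.sqrt(60)

    def test_labels_truth_and_assignment_count(self, geno, peaks):
        pop = _pop(ca_peaks=0.3)
        sim, truth = simulate_population(pop, geno, peaks, cells_per_individual=5, seed=3)
        assert sim.data.n_cells == 20 * 5
        assert sim.data.cells["individual"].nunique() == 20
        assert len(truth.caqtl) == round(0.3 * 200)

    def test_caqtl_effects_visible_in_pseudobulk(self, geno, peaks):
        pop = _pop(ca_peaks=0.5, alpha_c=4.0, beta_c=4.0, var_scale=0.3)
        sim, truth = simulate_population(pop, geno, peaks, cells_per_individual=40, seed=8)
        pb = aggregate_pseudobulk(sim, quantile_normalize=True)
        dosage_by_snp = {s: geno.dosages[:, k] for k, s in enumerate(geno.snps["id"])}
        ids = list(pb.columns)
        order = [geno.individuals.index(i) for i in ids]
        rs = []
        for a in truth.caqtl:
            g = dosage_by_snp[a.snp_id][order]
            if np.ptp(g) == 0:
                continue
            y = pb.loc[a.peak_id].to_numpy()
            rs.append(a.sign * np.corrcoef(g, y)[0, 1])
        assert np.mean(rs) > 0.1  # effects push pseudobulk in the signed direction


class TestPseudobulk:
    def test_single_cell_per_individual_is_normalized_profile(self, small_sim):
        data = small_sim.data
        sub = data.subset_cells(np.arange(3))
        sub.cells["individual"] = ["a", "b", "c"]
        pb = aggregate_pseudobulk(sub, normalize_cells=True)
        dense = sub.to_dense().astype(float)
        totals = dense.sum(axis=0)
        med = np.median(totals)
        np.testing.assert_allclose(pb["a"], dense[:, 0] * med / totals[0])

    def test_quantile_normalized_rows_standard(self, geno, peaks):
        rng = np.random.default_rng(0)
        from conftest import make_counts

        counts = make_counts(rng.poisson(3, (40, 30)))
        counts.cells["individual"] = np.repeat([f"i{k}" for k in range(10)], 3)
        pb = aggregate_pseudobulk(counts, quantile_normalize=True)
        m = pb.to_numpy()
        varying = m.std(axis=1) > 0
        assert np.abs(m[varying].mean(axis=1)).max() < 1e-9
        assert np.abs(m[varying].std(axis=1, ddof=1) - 1).max() < 1e-6

    def test_constant_matrix_constant_pseudobulk(self):
        from conftest import make_counts

        counts = make_counts(np.full((5, 6), 2))
        counts.cells["individual"] = ["a"] * 3 + ["b"] * 3
        pb = aggregate_pseudobulk(counts, normalize_cells=False)
        np.testing.assert_allclose(pb.to_numpy(), 2.0)

    def test_requires_individual_label(self, small_sim):
        with pytest.raises(ValueError, match="individual"):
            aggregate_pseudobulk(small_sim.data)
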