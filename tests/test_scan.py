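"""Window geometry, the windowed scan, permutation null and sweep detection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from popsweep import (
    GenotypeMatrix,
    PopulationMap,
    ScanConfig,
    SimulationConfig,
    SweepScan,
    SweepSpec,
    apply_missingness_and_depth,
    detect_sweep_regions,
    intersect_gene_sets,
    make_windows,
    permute_fst_null,
    scan_windows,
    simulate_genotypes,
    top_quantile_threshold,
    wc_fst,
)
from popsweep.io import GeneModel
from popsweep.scan import ScanConfigError, genes_in_regions
from popsweep.diversity import pi_sites

from conftest import make_matrix, two_pop_map


class TestMakeWindows:
    def test_non_overlapping_with_partial_tail(self):
        w = make_windows({"c": 25_000}, ScanConfig(window_size=10_000, step_size=10_000))
        assert len(w) == 3
        assert w["start"].tolist() == [1, 10_001, 20_001]
        assert w["end"].tolist() == [10_000, 20_000, 25_000]
        assert w["partial"].tolist() == [False, False, True]

    def test_window_longer_than_chromosome(self):
        w = make_windows({"c": 4_000}, ScanConfig(window_size=10_000, step_size=10_000))
        assert len(w) == 1 and w.iloc[0]["end"] == 4_000 and bool(w.iloc[0]["partial"])

    def test_overlapping_windows_every_step(self):
        w = make_windows({"c": 25_000}, ScanConfig(window_size=10_000, step_size=5_000))
        assert w["start"].tolist()[:4] == [1, 5_001, 10_001, 15_001]

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ScanConfigError):
            ScanConfig(window_size=0)
        with pytest.raises(ScanConfigError):
            ScanConfig(window_size=10, step_size=20)


def _sim(seed=17, sweep=True, n_sites=8_000, missing=0.05):
    specs = [SweepSpec("WZ", "chr1", 300_001, 350_000, 0.9)] if sweep else []
    cfg = SimulationConfig(
        n_pops=2, samples_per_pop=10, n_chroms=2, chrom_length=500_000,
        n_sites=n_sites, divergence_F=0.05, missing_rate=missing,
        sweep_specs=specs, pop_labels=("QZ", "WZ"), seed=seed,
    )
    gm, truth = simulate_genotypes(cfg)
    gm = apply_missingness_and_depth(gm, cfg)
    return cfg, gm, truth


class TestScanWindows:
    def test_fixed_difference_window_fst_one(self):
        calls = np.array([[0] * 5] * 4 + [[2] * 5] * 4, dtype=np.int8)
        gm = make_matrix(calls, positions=[100, 200, 300, 400, 500])
        pm = two_pop_map(4, sample_ids=gm.sample_ids)
        w = scan_windows(gm, pm, "QZ", "WZ", ScanConfig(), {"chr1": 1000})
        assert w.iloc[0]["fst"] == pytest.approx(1.0)

    def test_empty_window_undefined(self):
        gm = make_matrix(np.array([[1], [0], [1], [2]], dtype=np.int8),
                         positions=[15_000])
        pm = two_pop_map(2, sample_ids=gm.sample_ids)
        w = scan_windows(gm, pm, "QZ", "WZ", ScanConfig(), {"chr1": 20_000})
        assert np.isnan(w.iloc[0]["fst_raw"]) and w.iloc[0]["n_sites"] == 0
        assert w.iloc[1]["n_sites"] == 1

    def test_per_window_values_equal_sitewise_oracle(self):
        cfg, gm, _ = _sim(seed=21, sweep=False, n_sites=2_000)
        pm = cfg.population_map()
        w = scan_windows(gm, pm, "QZ", "WZ", ScanConfig(), cfg.chrom_lengths)
        idxA = gm.sample_indices(pm.samples("QZ"))
        idxB = gm.sample_indices(pm.samples("WZ"))
        chrom = gm.sites["chrom"].to_numpy()
        pos = gm.sites["pos"].to_numpy()
        checked = 0
        for _, row in w.sample(10, random_state=0).iterrows():
            sel = np.flatnonzero(
                (chrom == row["chrom"]) & (pos >= row["start"]) & (pos <= row["end"])
            )
            if len(sel) == 0:
                continue
            ref_fst = wc_fst(gm, idxA, idxB, sel)
            if np.isnan(ref_fst):
                assert np.isnan(row["fst_raw"])
            else:
                assert row["fst_raw"] == pytest.approx(ref_fst, abs=1e-10)
            for tag, idx in (("pi_ref", idxA), ("pi_focal", idxB)):
                _, nd, nc = pi_sites(gm.take_sites(sel), idx)
                assert row[tag] == pytest.approx(nd.sum() / nc.sum(), abs=1e-12)
            checked += 1
        assert checked >= 8

    def test_invariant_to_sample_order(self):
        cfg, gm, _ = _sim(seed=2, sweep=False, n_sites=1_000)
        pm = cfg.population_map()
        w1 = scan_windows(gm, pm, "QZ", "WZ", ScanConfig(), cfg.chrom_lengths)
        rng = np.random.default_rng(0)
        perm = rng.permutation(gm.n_samples)
        gm2 = gm.take_samples(perm)
        w2 = scan_windows(gm2, pm, "QZ", "WZ", ScanConfig(), cfg.chrom_lengths)
        pd.testing.assert_frame_equal(w1, w2)

    def test_population_swap_negates_log_ratio(self):
        cfg, gm, _ = _sim(seed=3, sweep=False, n_sites=1_000)
        pm = cfg.population_map()
        w1 = scan_windows(gm, pm, "QZ", "WZ", ScanConfig(), cfg.chrom_lengths)
        w2 = scan_windows(gm, pm, "WZ", "QZ", ScanConfig(), cfg.chrom_lengths)
        np.testing.assert_allclose(w1["fst_raw"], w2["fst_raw"], atol=1e-12)
        np.testing.assert_allclose(w1["pi_ref"], w2["pi_focal"], atol=1e-12)
        np.testing.assert_allclose(w1["log2_ratio"], -w2["log2_ratio"], atol=1e-12)

    def test_unknown_population_rejected(self):
        cfg, gm, _ = _sim(seed=4, sweep=False, n_sites=200)
        with pytest.raises(KeyError):
            scan_windows(gm, cfg.population_map(), "QZ", "XX", ScanConfig())


class TestPermutationNull:
    def test_pooled_size_and_quantile_convention(self):
        cfg, gm, _ = _sim(seed=5, sweep=False, n_sites=1_000, missing=0.0)
        pm = cfg.population_map()
        scfg = ScanConfig(n_permutations=2, permutation_seed=1)
        null = permute_fst_null(gm, pm, "QZ", "WZ", scfg, cfg.chrom_lengths)
        n_windows = len(make_windows(cfg.chrom_lengths, scfg))
        assert len(null.values) == 2 * n_windows
        assert null.percentile95 == pytest.approx(
            float(np.quantile(null.values, 0.95, method="linear")))

    def test_deterministic_given_seed(self):
        cfg, gm, _ = _sim(seed=6, sweep=False, n_sites=500)
        pm = cfg.population_map()
        scfg = ScanConfig(n_permutations=3, permutation_seed=9)
        n1 = permute_fst_null(gm, pm, "QZ", "WZ", scfg, cfg.chrom_lengths)
        n2 = permute_fst_null(gm, pm, "QZ", "WZ", scfg, cfg.chrom_lengths)
        np.testing.assert_array_equal(n1.values, n2.values)

    def test_small_groups_rejected(self):
        gm = make_matrix(np.array([[0, 1], [1, 2], [0, 0]], dtype=np.int8))
        pm = PopulationMap({"S1": "A", "S2": "A", "S3": "B"})
        with pytest.raises(ValueError):
            permute_fst_null(gm, pm, "A", "B", ScanConfig(n_permutations=1))

    def test_null_indistinguishable_from_observed_under_exchangeability(self):
        # one population split into two arbitrary halves: labels carry no signal,
        # so observed window FSTs and pooled permuted values share a distribution
        cfg = SimulationConfig(n_pops=1, samples_per_pop=20, n_chroms=1,
                               chrom_length=5_000_000, n_sites=5_000,
                               divergence_F=0.1, missing_rate=0.05,
                               pop_labels=("ALL",), seed=13)
        gm, _ = simulate_genotypes(cfg)
        gm = apply_missingness_and_depth(gm, cfg)
        pm = PopulationMap(
            {s: ("A" if i < 10 else "B") for i, s in enumerate(gm.sample_ids)})
        scfg = ScanConfig(n_permutations=20, permutation_seed=13)
        w = scan_windows(gm, pm, "A", "B", scfg, cfg.chrom_lengths)
        null = permute_fst_null(gm, pm, "A", "B", scfg, cfg.chrom_lengths)
        obs = w["fst_raw"].dropna().to_numpy()
        assert len(obs) == 500
        ks = stats.ks_2samp(obs, null.values)
        assert ks.pvalue > 0.01


class TestTopQuantile:
    def test_linear_interpolation_on_1_to_100(self):
        thr, idx = top_quantile_threshold(np.arange(1.0, 101.0), 0.05)
        assert thr == pytest.approx(95.05)
        assert idx.tolist() == [95, 96, 97, 98, 99]

    def test_all_equal_all_flagged(self):
        thr, idx = top_quantile_threshold(np.full(7, 3.3), 0.05)
        assert thr == 3.3 and len(idx) == 7

    def test_single_value(self):
        thr, idx = top_quantile_threshold(np.array([2.5]), 0.05)
        assert thr == 2.5 and idx.tolist() == [0]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            top_quantile_threshold(np.array([np.nan]), 0.05)


class TestDetectSweepRegions:
    def test_planted_sweep_recovered(self):
        cfg, gm, _ = _sim(seed=17, sweep=True, n_sites=20_000)
        pm = cfg.population_map()
        res = SweepScan(gm, pm, "QZ", "WZ", ScanConfig(),
                        chrom_lengths=cfg.chrom_lengths).fit(permute=False)
        assert any(
            r.chrom == "chr1" and r.start <= 350_000 and r.end >= 300_001
            for r in res.regions
        )

    def test_no_sweep_candidate_fraction_small(self):
        cfg, gm, _ = _sim(seed=18, sweep=False, n_sites=20_000)
        pm = cfg.population_map()
        res = SweepScan(gm, pm, "QZ", "WZ", ScanConfig(),
                        chrom_lengths=cfg.chrom_lengths).fit(permute=False)
        n_candidate = sum(len(r.window_index) for r in res.regions)
        n_windows = len(res.windows)
        # joint tail of two (correlated) 5% screens stays well below 5%
        assert n_candidate / n_windows < 0.05

    def test_adjacent_candidates_merge(self):
        w = pd.DataFrame(
            {
                "chrom": ["c"] * 4,
                "start": [1, 10_001, 20_001, 40_001],
                "end": [10_000, 20_000, 30_000, 50_000],
                "partial": False,
                "n_sites": 5,
                "fst_raw": [0.9, 0.8, 0.01, 0.02],
                "fst": [0.9, 0.8, 0.01, 0.02],
                "pi_ref": [0.3, 0.3, 0.3, 0.3],
                "pi_focal": [0.01, 0.01, 0.3, 0.3],
                "log2_ratio": [4.9, 4.9, 0.0, 0.0],
            }
        )
        regions, _, _ = detect_sweep_regions(w, ScanConfig(top_quantile=0.5))
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (1, 20_000)

    def test_order_invariant(self):
        cfg, gm, _ = _sim(seed=19, sweep=True, n_sites=6_000)
        pm = cfg.population_map()
        w = scan_windows(gm, pm, "QZ", "WZ", ScanConfig(), cfg.chrom_lengths)
        r1, *_ = detect_sweep_regions(w, ScanConfig())
        shuffled = w.sample(frac=1, random_state=3).reset_index(drop=True)
        r2, *_ = detect_sweep_regions(shuffled, ScanConfig())
        assert [(r.chrom, r.start, r.end) for r in r1] == [
            (r.chrom, r.start, r.end) for r in r2]

    def test_zero_focal_pi_counts_as_extreme_ratio(self):
        w = pd.DataFrame(
            {
                "chrom": ["c"] * 3,
                "start": [1, 10_001, 20_001],
                "end": [10_000, 20_000, 30_000],
                "partial": False,
                "n_sites": 5,
                "fst_raw": [0.9, 0.1, 0.1],
                "fst": [0.9, 0.1, 0.1],
                "pi_ref": [0.3, 0.3, 0.0],
                "pi_focal": [0.0, 0.3, 0.0],
                "log2_ratio": [np.inf, 0.0, np.nan],
            }
        )
        regions, _, _ = detect_sweep_regions(w, ScanConfig(top_quantile=0.4))
        assert [(r.start, r.end) for r in regions] == [(1, 10_000)]


class TestGeneAssociation:
    GENES = [
        GeneModel("g1", "c1", "+", 100, 900),
        GeneModel("g2", "c1", "-", 5_000, 6_000),
        GeneModel("g3", "c1", "+", 10_000, 10_050),
        GeneModel("g4", "c2", "+", 100, 400),
        GeneModel("g5", "c2", "-", 2_000, 2_400),
    ]

    def test_hand_enumerated_association(self):
        from popsweep.scan import SweepRegion

        regions = [SweepRegion("c1", 800, 5_500), SweepRegion("c2", 500, 2_000)]
        table, flat = genes_in_regions(regions, self.GENES)
        assert table[("c1", 800, 5_500)] == ["g1", "g2"]
        assert table[("c2", 500, 2_000)] == ["g5"]
        assert flat == ["g1", "g2", "g5"]

    def test_one_bp_off_is_not_associated(self):
        from popsweep.scan import SweepRegion

        regions = [SweepRegion("c1", 901, 4_999)]
        table, flat = genes_in_regions(regions, self.GENES)
        assert flat == []

    def test_chromosome_name_mismatch_is_explicit_error(self):
        from popsweep.scan import SweepRegion

        with pytest.raises(ValueError, match="chrX"):
            genes_in_regions([SweepRegion("chrX", 1, 10)], self.GENES)


class TestIntersectGeneSets:
    def test_ordered_intersection(self):
        assert intersect_gene_sets(["a", "b", "c"], ["b", "c", "d"]) == ["b", "c"]

    def test_disjoint_empty(self):
        assert intersect_gene_sets(["a"], ["b"]) == []

    def test_duplicates_collapsed(self):
        assert intersect_gene_sets(["a", "a", "b"], ["a", "b", "b"]) == ["a", "b"]


class TestModelInterface:
    def test_fit_returns_summary_and_tables(self, tmp_path):
        cfg, gm, _ = _sim(seed=23, sweep=True, n_sites=4_000)
        pm = cfg.population_map()
        model = SweepScan(gm, pm, "QZ", "WZ",
                          ScanConfig(n_permutations=5),
                          chrom_lengths=cfg.chrom_lengths)
        res = model.fit()
        text = res.summary()
        assert "permutation null" in text and "sweep regions" in text
        res.windows_to_tsv(tmp_path / "w.tsv")
        res.regions_to_bed(tmp_path / "r.bed")
        assert (tmp_path / "w.tsv").exists() and (tmp_path / "r.bed").exists()

    def test_manhattan_plot_builds(self):
        import matplotlib

        matplotlib.use("Agg")
        cfg, gm, _ = _sim(seed=24, sweep=False, n_sites=1_000)
        res = SweepScan(gm, cfg.population_map(), "QZ", "WZ", ScanConfig(),
                        chrom_lengths=cfg.chrom_lengths).fit(permute=False)
        ax = res.plot_manhattan()
        assert ax.get_ylabel()
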