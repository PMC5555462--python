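import numpy as np
import pandas as pd
import pytest
from scipy import stats

import rcscan as rc
from rcscan.scan import AlignmentError, GenomeScan, call_regions
from rcscan.simulate import CODE_A, CODE_B, GenotypePanel


def panel_from_dosage(dosage, small_map, strains=None):
    dosage = np.asarray(dosage)
    matrix = np.where(dosage == 1, CODE_A, CODE_B).astype(np.int8)
    strains = strains or [f"s{i}" for i in range(len(matrix))]
    return GenotypePanel(matrix, strains, ["BcA"] * len(matrix), small_map)


@pytest.fixture(scope="module")
def toy_scan_inputs(small_map):
    """Six strains; the first column of chromosome 4 carries a clean split."""
    rng = np.random.default_rng(5)
    dosage = rng.integers(0, 2, size=(6, small_map.n_markers))
    col = small_map.marker_index("c4_1")
    dosage[:, col] = [0, 0, 0, 1, 1, 1]
    y = pd.Series(
        [1.0, 2.0, 3.0, 11.0, 12.0, 13.0], index=[f"s{i}" for i in range(6)]
    )
    return y, panel_from_dosage(dosage, small_map)


class TestFitMarker:
    def test_toy_slope_and_t_test_duality(self, toy_scan_inputs, small_map):
        y, panel = toy_scan_inputs
        res = GenomeScan(y, panel, min_class_size=3).fit()
        row = res.scan.set_index("marker").loc["c4_1"]
        assert row["beta"] == pytest.approx(10.0)
        oracle = stats.ttest_ind([11, 12, 13], [1, 2, 3]).pvalue
        assert row["p"] == pytest.approx(oracle, rel=1e-12)
        assert row["neg_log10_p"] == pytest.approx(-np.log10(row["p"]))

    def test_monomorphic_marker_skipped(self, small_map):
        dosage = np.ones((6, small_map.n_markers), dtype=int)
        dosage[:, 1:] = np.random.default_rng(0).integers(
            0, 2, (6, small_map.n_markers - 1)
        )
        panel = panel_from_dosage(dosage, small_map)
        y = pd.Series(np.arange(6.0), index=panel.strain_ids)
        res = GenomeScan(y, panel, min_class_size=1).fit()
        first = res.scan.iloc[0]
        assert first["skipped"]
        assert first["skip_reason"] == "monomorphic"
        assert np.isnan(first["p"])

    def test_small_class_skipped_with_reason(self, small_map):
        rng = np.random.default_rng(2)
        dosage = rng.integers(0, 2, (8, small_map.n_markers))
        dosage[:, 0] = [1, 0, 0, 0, 0, 0, 0, 0]  # minor class of 1
        panel = panel_from_dosage(dosage, small_map)
        y = pd.Series(rng.normal(size=8), index=panel.strain_ids)
        res = GenomeScan(y, panel, min_class_size=3).fit()
        assert res.scan.iloc[0]["skip_reason"] == "class_size<3"

    def test_row_permutation_invariance(self, toy_scan_inputs, small_map):
        y, panel = toy_scan_inputs
        base = GenomeScan(y, panel).fit().scan
        order = [3, 0, 5, 2, 4, 1]
        strains = [y.index[i] for i in order]
        shuffled = GenomeScan(
            y.loc[strains], panel.subset(strains)
        ).fit().scan
        pd.testing.assert_frame_equal(base, shuffled)

    def test_heterozygous_calls_dropped_per_marker(self, small_map):
        rng = np.random.default_rng(3)
        dosage = rng.integers(0, 2, (10, small_map.n_markers))
        matrix = np.where(dosage == 1, CODE_A, CODE_B).astype(np.int8)
        matrix[0, 0] = 2  # H call at the first marker
        panel = GenotypePanel(
            matrix, [f"s{i}" for i in range(10)], ["BcA"] * 10, small_map
        )
        y = pd.Series(rng.normal(size=10), index=panel.strain_ids)
        res = GenomeScan(y, panel, min_class_size=2).fit()
        row = res.scan.iloc[0]
        if not row["skipped"]:
            assert row["n_used"] == 9
            g = panel.dosage()[1:, 0]
            oracle = stats.ttest_ind(
                y.to_numpy()[1:][g == 1], y.to_numpy()[1:][g == 0]
            ).pvalue
            assert row["p"] == pytest.approx(oracle, rel=1e-10)

    def test_strain_mismatch_reports_offenders(self, toy_scan_inputs):
        y, panel = toy_scan_inputs
        bad = y.rename(index={"s0": "ghost"})
        with pytest.raises(AlignmentError, match="ghost"):
            GenomeScan(bad, panel)


class TestStrainMeans:
    def test_mean_log2(self, pheno_factory):
        pheno = pheno_factory({"s1": [4, 16]})
        means = rc.strain_means(pheno, "baseline")
        assert means["s1"] == pytest.approx(3.0)

    def test_absent_condition_empty_with_warning(self, pheno_factory, caplog):
        pheno = pheno_factory({"s1": [4, 16]})
        means = rc.strain_means(pheno, "OVA-OVA")
        assert means.empty

    def test_exclusion_of_parental_strains(self, pheno_factory):
        pheno = pheno_factory({"s1": [4], "A/J": [8], "C57BL/6J": [2]})
        means = rc.strain_means(pheno, "baseline", exclude=("A/J", "C57BL/6J"))
        assert list(means.index) == ["s1"]

    def test_round_trip_through_noise_free_generator(self, bred_panel):
        qtl = rc.QtlSpec(
            effects=(rc.QtlEffect("c4_13", 2.0),),
            strain_variance=0.0, residual_variance=0.0,
        )
        pheno = rc.simulate_phenotypes(bred_panel, qtl, seed=0)
        means = rc.strain_means(pheno, "baseline")
        col = bred_panel.marker_map.marker_index("c4_13")
        for i, s in enumerate(bred_panel.strain_ids):
            expected = 7.0 + (2.0 if bred_panel.matrix[i, col] == CODE_A else 0.0)
            assert means[s] == pytest.approx(expected)


class TestQuantileRule:
    def test_integer_grid(self):
        values = np.arange(1, 101)
        assert rc.quantile_rule(values, 0.95) == 95

    def test_q1_is_maximum_and_q0_is_minimum(self):
        values = np.array([3.0, 1.0, 2.0])
        assert rc.quantile_rule(values, 1.0) == 3.0
        assert rc.quantile_rule(values, 0.0) == 1.0

    def test_matches_brute_force_sort(self):
        rng = np.random.default_rng(0)
        draws = rng.normal(size=10_000)
        assert rc.quantile_rule(draws, 0.95) == np.sort(draws)[9500 - 1]

    def test_errors(self):
        with pytest.raises(ValueError):
            rc.quantile_rule(np.array([]), 0.5)
        with pytest.raises(ValueError):
            rc.quantile_rule(np.array([1.0]), 1.5)


@pytest.fixture(scope="module")
def fitted(bred_panel):
    rng = np.random.default_rng(17)
    y = pd.Series(rng.normal(size=bred_panel.n_strains),
                  index=bred_panel.strain_ids)
    return GenomeScan(y, bred_panel, condition="baseline").fit()


class TestPermutationThreshold:
    def test_seed_reproducibility(self, fitted):
        t1 = fitted.permutation_threshold(n_perm=300, seed=1)
        t2 = fitted.permutation_threshold(n_perm=300, seed=1)
        assert t1.threshold_neg_log10 == t2.threshold_neg_log10

    def test_alpha_monotonicity(self, fitted):
        t05 = fitted.permutation_threshold(alpha=0.05, n_perm=500, seed=2)
        t01 = fitted.permutation_threshold(alpha=0.01, n_perm=500, seed=2)
        assert t01.threshold_neg_log10 >= t05.threshold_neg_log10

    def test_alpha_one_keeps_everything(self, fitted):
        maxima = fitted.permutation_maxima(300, seed=3)
        thr = fitted.permutation_threshold(alpha=1.0, n_perm=300, seed=3)
        assert thr.threshold_neg_log10 == pytest.approx(maxima.min())

    def test_dual_scale_consistency(self, fitted):
        thr = fitted.permutation_threshold(n_perm=200, seed=4)
        assert thr.threshold_p == pytest.approx(
            10 ** (-thr.threshold_neg_log10), rel=0, abs=0
        )

    def test_relabeling_invariance(self, bred_panel):
        # permutation thresholds depend on the multiset of strain means, not
        # on which strain carries which value
        rng = np.random.default_rng(18)
        vals = rng.normal(size=bred_panel.n_strains)
        y1 = pd.Series(vals, index=bred_panel.strain_ids)
        t1 = GenomeScan(y1, bred_panel).fit().permutation_threshold(
            n_perm=300, seed=5
        )
        shuffled = rng.permutation(vals)
        y2 = pd.Series(shuffled, index=bred_panel.strain_ids)
        t2 = GenomeScan(y2, bred_panel).fit().permutation_threshold(
            n_perm=300, seed=5
        )
        assert t1.threshold_neg_log10 == pytest.approx(
            t2.threshold_neg_log10, abs=1e-9
        )

    def test_invalid_parameters(self, fitted):
        with pytest.raises(ValueError):
            fitted.permutation_threshold(alpha=0.0, n_perm=200)
        with pytest.raises(ValueError):
            fitted.permutation_threshold(alpha=0.05, n_perm=50)


def _scan_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["marker", "chrom", "pos_mbp", "p", "skipped"],
    ).assign(
        neg_log10_p=lambda d: -np.log10(d["p"]),
        skip_reason="",
    )


class TestRegions:
    THR = rc.ThresholdSet("baseline", 0.05, 1000, 3.5)

    def test_no_significant_markers(self):
        scan = _scan_frame([("m1", "4", 80.0, 0.5, False)])
        assert call_regions(scan, self.THR) == []

    def test_adjacent_significant_markers_single_region(self):
        # mirrors a two-marker significant run flanked by null markers
        scan = _scan_frame(
            [
                ("m0", "4", 75.0, 0.9, False),
                ("m1", "4", 81.46, 1e-4, False),
                ("m2", "4", 86.17, 2e-4, False),
                ("m3", "4", 90.0, 0.5, False),
            ]
        )
        regions = call_regions(scan, self.THR)
        assert len(regions) == 1
        r = regions[0]
        assert (r.start_mbp, r.end_mbp) == (81.46, 86.17)
        assert r.peak_marker == "m1"
        assert r.peak_p == pytest.approx(1e-4)

    def test_regions_never_span_chromosomes(self):
        scan = _scan_frame(
            [
                ("m1", "4", 150.0, 1e-5, False),
                ("m2", "5", 1.0, 1e-5, False),
            ]
        )
        regions = call_regions(scan, self.THR)
        assert len(regions) == 2
        assert {r.chromosome for r in regions} == {"4", "5"}

    def test_nonsignificant_marker_splits_but_skipped_does_not(self):
        scan = _scan_frame(
            [
                ("m1", "4", 10.0, 1e-4, False),
                ("m2", "4", 12.0, np.nan, True),
                ("m3", "4", 14.0, 1e-4, False),
                ("m4", "4", 16.0, 0.9, False),
                ("m5", "4", 18.0, 1e-4, False),
            ]
        )
        regions = call_regions(scan, self.THR)
        assert [(r.start_mbp, r.end_mbp) for r in regions] == [
            (10.0, 14.0),
            (18.0, 18.0),
        ]

    def test_gap_tolerance_merges_across_one_null_marker(self):
        scan = _scan_frame(
            [
                ("m1", "4", 10.0, 1e-4, False),
                ("m2", "4", 12.0, 0.9, False),
                ("m3", "4", 14.0, 1e-4, False),
            ]
        )
        merged = call_regions(scan, self.THR, max_gap=1)
        assert [(r.start_mbp, r.end_mbp) for r in merged] == [(10.0, 14.0)]

    def test_idempotence_against_rethresholding(self, bred_panel):
        rng = np.random.default_rng(23)
        y = pd.Series(rng.normal(size=bred_panel.n_strains),
                      index=bred_panel.strain_ids)
        res = GenomeScan(y, bred_panel, condition="c").fit()
        thr = rc.ThresholdSet("c", 0.05, 1000, 1.5)
        whole = res.call_regions(thr)
        per_chrom = []
        for chrom in dict.fromkeys(res.scan["chrom"]):
            sub = res.scan[res.scan["chrom"] == chrom]
            per_chrom.extend(call_regions(sub, thr, condition="c"))
        assert rc.regions_to_frame(whole).equals(rc.regions_to_frame(per_chrom))
        for r in whole:
            inside = res.scan[
                (res.scan["chrom"] == r.chromosome)
                & res.scan["pos_mbp"].between(r.start_mbp, r.end_mbp)
                & ~res.scan["skipped"]
            ]
            assert (inside["p"] <= thr.threshold_p).all()
            assert r.peak_p <= thr.threshold_p


class TestPlantedQtlRecovery:
    def test_peak_lands_at_or_near_planted_marker(self, small_map):
        # smoke-scale recovery check; the full-scale rate is measured in the
        # acceptance suite
        hits = 0
        for seed in range(5):
            ss = np.random.SeedSequence(seed).spawn(3)
            panel = rc.breed_rcs_panel(
                rc.BreedingConfig(seed=ss[0].generate_state(1)[0] % 2 ** 31),
                small_map,
            )
            qtl = rc.QtlSpec(effects=(rc.QtlEffect("c4_13", 2.0),))
            pheno = rc.simulate_phenotypes(
                panel, qtl, n_per_strain=(10, 10),
                rng=np.random.default_rng(ss[1]),
            )
            res = rc.GenomeScan.from_panels(pheno, panel, "baseline").fit()
            tested = res.scan[~res.scan["skipped"]]
            top = tested.loc[tested["p"].idxmin()]
            if top["chrom"] == "4":
                hits += 1
        assert hits >= 4
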