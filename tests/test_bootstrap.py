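import numpy as np
import pandas as pd
import pytest

from stableboot import (
    BootstrapConfig,
    CountDataset,
    FrequencyTable,
    SyntheticDesign,
    balance_groups,
    bootstrap_frequencies,
    calibrate_ratio,
    call_stable_genes,
    draw_subset,
    estimate_min_sample_size,
    run_de,
    saturation_curve,
    simulate_dataset,
)


class TestConfig:
    def test_threshold_arithmetic(self):
        cfg = BootstrapConfig(subset_sizes=tuple(range(3, 12)), n_repeats=1000)
        assert cfg.planned_comparisons == 9000
        assert cfg.per_size_cutoff == pytest.approx(300)
        # default: same ratio drives both cutoffs
        assert cfg.overall_cutoff == pytest.approx(2700)
        # human-study convention: overall cutoff is one third of 9,000
        from stableboot import human_study_config
        assert human_study_config().overall_cutoff == pytest.approx(3000)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            BootstrapConfig(subset_sizes=(3, 3, 4))
        with pytest.raises(ValueError, match="ratio"):
            BootstrapConfig(ratio=0.0)
        with pytest.raises(ValueError, match="n_repeats"):
            BootstrapConfig(n_repeats=0)
        cfg = BootstrapConfig(subset_sizes=(3, 4))
        with pytest.raises(ValueError, match="smaller than"):
            cfg.validate_units(4)


class TestDrawSubset:
    def test_full_draw_is_exhaustive(self, rng):
        units = [f"s{i}" for i in range(5)]
        assert draw_subset(units, 5, rng) == sorted(units)

    def test_fixed_seed_reproduces_subset(self):
        units = list("abcdefghijkl")
        a = draw_subset(units, 3, np.random.default_rng(9))
        b = draw_subset(units, 3, np.random.default_rng(9))
        assert a == b

    def test_oversized_draw_rejected(self, rng):
        with pytest.raises(ValueError, match="cannot draw"):
            draw_subset(list("abc"), 4, rng)

    def test_inclusion_uniformity(self):
        # each of 12 subjects should appear with frequency ~ 3/12 over
        # 10,000 draws of size 3 (binomial 3-sigma band)
        units = [f"s{i}" for i in range(12)]
        rng = np.random.default_rng(2024)
        hits = {u: 0 for u in units}
        n = 10_000
        for _ in range(n):
            for u in draw_subset(units, 3, rng):
                hits[u] += 1
        p = 3 / 12
        sigma = np.sqrt(n * p * (1 - p))
        for u in units:
            assert abs(hits[u] - n * p) < 3 * sigma

    def test_unpaired_draw_per_group(self, rng):
        units = {"group1": list("abcde"), "group2": list("vwxyz")}
        out = draw_subset(units, 3, rng, paired=False)
        assert len(out["group1"]) == 3 and len(out["group2"]) == 3
        assert set(out["group1"]) <= set(units["group1"])


def _unpaired_dataset(n1, n2, seed=0):
    rng = np.random.default_rng(seed)
    n = n1 + n2
    counts = pd.DataFrame(rng.integers(0, 60, size=(30, n)),
                          index=[f"g{i}" for i in range(30)],
                          columns=[f"c{j}" for j in range(n)])
    meta = pd.DataFrame({
        "sample_id": counts.columns,
        "subject_id": counts.columns,
        "group": ["group1"] * n1 + ["group2"] * n2,
    })
    return CountDataset(counts, meta)


class TestBalanceGroups:
    def test_downsamples_larger_group(self):
        ds = _unpaired_dataset(73, 170)
        out, info = balance_groups(ds, np.random.default_rng(1))
        sizes = out.meta["group"].value_counts()
        assert sizes["group1"] == 73 and sizes["group2"] == 73
        assert info["downsampled_group"] == "group2"
        assert len(info["dropped"]) == 97

    def test_balanced_is_identity_with_notice(self):
        ds = _unpaired_dataset(5, 5)
        out, info = balance_groups(ds, np.random.default_rng(1))
        assert info["already_balanced"]
        assert out.sample_ids == ds.sample_ids

    def test_same_seed_same_selection(self):
        ds = _unpaired_dataset(10, 20)
        a, ia = balance_groups(ds, np.random.default_rng(5))
        b, ib = balance_groups(ds, np.random.default_rng(5))
        assert ia["kept"] == ib["kept"]
        assert a.sample_ids == b.sample_ids


@pytest.fixture(scope="module")
def strong_run():
    """Small strong-effect cohort with a completed bootstrap run."""
    design = SyntheticDesign(n_subjects=8, n_genes=400, frac_de=0.05,
                             log2fc_low=2.5, log2fc_high=4.0, seed=42)
    ds, truth = simulate_dataset(design)
    cfg = BootstrapConfig(subset_sizes=(3, 4, 5), n_repeats=40, seed=42)
    freq = bootstrap_frequencies(ds, cfg)
    return ds, truth, cfg, freq


class TestBootstrapFrequencies:
    def test_comparison_count_and_bounds(self, strong_run):
        _, _, cfg, freq = strong_run
        assert cfg.planned_comparisons == 3 * 40
        for d in freq.directions:
            arr = freq.counts[d].to_numpy()
            assert arr.min() >= 0 and arr.max() <= cfg.n_repeats

    def test_single_draw_full_cohort_equals_full_de(self, strong_run):
        ds, _, _, _ = strong_run
        # n_repeats = 1 with the near-full cohort: frequencies are exactly
        # the DEG indicator of that single DE analysis
        cfg = BootstrapConfig(subset_sizes=(7,), n_repeats=1, seed=0)
        freq = bootstrap_frequencies(ds, cfg)
        subjects = sorted(ds.subjects_with_both_groups())
        chosen = draw_subset(
            subjects, 7,
            np.random.default_rng(np.random.SeedSequence(0, spawn_key=(7, 0))))
        keep = [s for s in ds.sample_ids
                if ds.meta.loc[s, "subject_id"] in chosen]
        full = run_de(ds.subset_samples(keep))
        total = freq.totals(freq.directions[0]) + freq.totals(freq.directions[1])
        assert set(total.index[total == 1]) == set(full.degs.index)

    def test_bit_reproducible_with_same_seed(self, strong_run):
        ds, _, cfg, freq = strong_run
        again = bootstrap_frequencies(ds, cfg)
        for d in freq.directions:
            pd.testing.assert_frame_equal(freq.counts[d], again.counts[d])
        pd.testing.assert_frame_equal(freq.detected_any, again.detected_any)

    def test_distinct_subset_logging(self, strong_run):
        _, _, cfg, freq = strong_run
        for size in cfg.subset_sizes:
            assert 1 <= freq.n_distinct_subsets[size] <= cfg.n_repeats

    def test_save_load_roundtrip(self, strong_run, tmp_path):
        _, _, _, freq = strong_run
        freq.save(tmp_path / "f")
        back = FrequencyTable.load(tmp_path / "f")
        for d in freq.directions:
            pd.testing.assert_frame_equal(freq.counts[d], back.counts[d])
        assert back.config == freq.config
        assert back.n_distinct_subsets == freq.n_distinct_subsets


def _toy_freq(up_totals, down_totals, sizes=(3, 4, 5), n_repeats=1000):
    """Hand-built FrequencyTable spreading totals evenly over sizes."""
    genes = pd.Index(sorted(up_totals), name="gene")
    n_sizes = len(sizes)
    def spread(totals):
        rows = []
        for g in genes:
            t = totals[g]
            base = t // n_sizes
            rem = t - base * n_sizes
            rows.append([base + (1 if i < rem else 0) for i in range(n_sizes)])
        return pd.DataFrame(rows, index=genes, columns=list(sizes))
    up = spread(up_totals)
    down = spread(down_totals)
    det = (up + down) > 0
    cfg = BootstrapConfig(subset_sizes=sizes, n_repeats=n_repeats)
    return FrequencyTable(
        genes=genes, sizes=sizes, n_repeats=n_repeats,
        group_order=("group1", "group2"),
        counts={"group1_enriched": down, "group2_enriched": up},
        padj_sum={"group1_enriched": pd.Series(0.01, index=genes) * down.sum(axis=1),
                  "group2_enriched": pd.Series(0.01, index=genes) * up.sum(axis=1)},
        detected_any=det,
        mean_degs_per_draw=pd.Series(0.0, index=list(sizes)),
        n_distinct_subsets={s: 1 for s in sizes},
        config=cfg,
    )


class TestCallStableGenes:
    def test_strict_threshold_at_cutoff(self):
        # 3 sizes x 1000 repeats at ratio 0.30 -> overall cutoff 900:
        # a gene at 901 is stable, a gene at exactly 900 is not
        freq = _toy_freq({"gA": 901, "gB": 900, "gC": 0},
                         {"gA": 0, "gB": 0, "gC": 10})
        rep = call_stable_genes(freq)
        assert rep.overall_cutoff == pytest.approx(900)
        assert rep.stable_genes == ["gA"]

    def test_per_size_cutoff_value(self):
        cfg = BootstrapConfig(subset_sizes=(5,), n_repeats=1000, ratio=0.30)
        assert cfg.per_size_cutoff == pytest.approx(300)

    def test_direction_conflict_excluded_and_flagged(self):
        freq = _toy_freq({"gA": 950, "gB": 999}, {"gA": 940, "gB": 0})
        rep = call_stable_genes(freq)
        assert rep.direction_unstable == ["gA"]
        assert rep.stable_genes == ["gB"]

    def test_ranking_by_total_then_padj_then_id(self):
        freq = _toy_freq({"gA": 950, "gB": 980, "gC": 950, "gD": 0},
                         {"gA": 0, "gB": 0, "gC": 0, "gD": 990})
        rep = call_stable_genes(freq)
        up = rep.table[rep.table["direction"] == "group2_enriched"]
        assert list(up.index) == ["gB", "gA", "gC"]  # total desc, then id
        assert list(up["rank"]) == [1, 2, 3]
        down = rep.table[rep.table["direction"] == "group1_enriched"]
        assert list(down.index) == ["gD"]

    def test_stable_subset_of_detected_union(self, strong_run):
        _, _, _, freq = strong_run
        rep = call_stable_genes(freq)
        detected_ever = set(freq.genes[freq.detected_any.any(axis=1)])
        assert set(rep.stable_genes) <= detected_ever

    def test_recovers_planted_genes(self, strong_run):
        ds, truth, _, freq = strong_run
        rep = call_stable_genes(freq)
        planted = set(truth.index[truth["is_de"]])
        stable = set(rep.stable_genes)
        assert len(stable & planted) / len(planted) >= 0.8


class TestCalibrateRatio:
    def test_overlap_against_set_intersection_oracle(self, strong_run):
        ds, _, _, freq = strong_run
        full = run_de(ds)
        table = calibrate_ratio(freq, full, ratios=[0.3])
        stable = set(call_stable_genes(freq).stable_genes)
        ranked = full.degs.sort_values("padj").index.tolist()
        for frac in (0.1, 0.3, 1.0):
            k = int(np.ceil(frac * len(ranked)))
            expected = 100.0 * len(stable & set(ranked[:k])) / len(stable)
            col = f"overlap_top_{int(frac * 100)}pct"
            assert table.loc[0, col] == pytest.approx(expected)

    def test_full_overlap_at_every_fraction_when_stable_in_top(self):
        freq = _toy_freq({"gA": 950, "gB": 0}, {"gA": 0, "gB": 0})
        degs = pd.DataFrame({"padj": [1e-10, 1e-8, 1e-6]},
                            index=["gA", "gX", "gY"])
        table = calibrate_ratio(freq, degs, ratios=[0.3])
        for frac in range(10, 101, 10):
            assert table.loc[0, f"overlap_top_{frac}pct"] == pytest.approx(100.0)

    def test_ratio_one_reports_vacuously(self):
        freq = _toy_freq({"gA": 500}, {"gA": 0})
        degs = pd.DataFrame({"padj": [1e-4]}, index=["gA"])
        table = calibrate_ratio(freq, degs, ratios=[1.0])
        assert table.loc[0, "n_stable"] == 0
        assert np.isnan(table.loc[0, "overlap_top_10pct"])

    def test_empty_deg_list_is_explicit_error(self):
        freq = _toy_freq({"gA": 500}, {"gA": 0})
        with pytest.raises(ValueError, match="calibration undefined"):
            calibrate_ratio(freq, pd.DataFrame({"padj": []}), ratios=[0.3])


class TestSaturation:
    def _freq_with_sets(self, per_size_sets, sizes):
        genes = sorted(set().union(*per_size_sets))
        det = pd.DataFrame(False, index=pd.Index(genes, name="gene"),
                           columns=list(sizes))
        for s, gene_set in zip(sizes, per_size_sets):
            det.loc[sorted(gene_set), s] = True
        cfg = BootstrapConfig(subset_sizes=sizes, n_repeats=10)
        zeros = pd.DataFrame(0, index=det.index, columns=list(sizes))
        return FrequencyTable(
            genes=det.index, sizes=sizes, n_repeats=10,
            group_order=("group1", "group2"),
            counts={"group1_enriched": zeros, "group2_enriched": zeros.copy()},
            padj_sum={"group1_enriched": pd.Series(0.0, index=det.index),
                      "group2_enriched": pd.Series(0.0, index=det.index)},
            detected_any=det,
            mean_degs_per_draw=pd.Series(0.0, index=list(sizes)),
            n_distinct_subsets={s: 1 for s in sizes}, config=cfg)

    def test_set_arithmetic(self):
        freq = self._freq_with_sets([{"A", "B"}, {"A", "B"}, {"A", "B", "C"}],
                                    sizes=(3, 4, 5))
        curve = saturation_curve(freq)
        assert list(curve["novel"]) == [2, 0, 1]
        assert list(curve["cumulative_distinct"]) == [2, 2, 3]

    def test_identical_sets_give_zero_novel_after_first(self):
        freq = self._freq_with_sets([{"A", "B", "C"}] * 4, sizes=(3, 4, 5, 6))
        curve = saturation_curve(freq)
        assert list(curve["novel"]) == [3, 0, 0, 0]

    def test_matches_union_oracle_on_synthetic_run(self, strong_run):
        _, _, _, freq = strong_run
        curve = saturation_curve(freq)
        seen = set()
        for s in freq.sizes:
            current = set(freq.genes[freq.detected_any[s]])
            assert curve.loc[s, "novel"] == len(current - seen)
            seen |= current
            assert curve.loc[s, "cumulative_distinct"] == len(seen)


class TestMinSampleSize:
    def _curve(self, novel, sizes):
        cum = np.cumsum(novel)
        return pd.DataFrame({"novel": novel, "cumulative_distinct": cum},
                            index=pd.Index(sizes, name="size"))

    def test_hand_applied_rule(self):
        curve = self._curve([40, 12, 6, 3, 1, 0], sizes=range(3, 9))
        assert estimate_min_sample_size(curve, tol_abs=5) == 6

    def test_all_zero_novel_returns_smallest_size(self):
        curve = self._curve([0, 0, 0], sizes=[3, 4, 5])
        assert estimate_min_sample_size(curve) == 3

    def test_never_below_tolerance_not_reached(self):
        curve = self._curve([100, 100, 100], sizes=[3, 4, 5])
        assert estimate_min_sample_size(curve, tol_abs=5, tol_frac=0.01) is None

    def test_short_curve_rejected(self):
        curve = self._curve([5, 3], sizes=[3, 4])
        with pytest.raises(ValueError, match=">= 3 sizes"):
            estimate_min_sample_size(curve)
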