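"""Tests for the TMT quantitation and significance pipeline, operation by
operation and end-to-end (channel-scale invariance, ratio symmetry)."""

import numpy as np
import pandas as pd
import pytest

from mitophos import (
    CutoffModel,
    DataError,
    GeneratorConfig,
    annotate_stp_motif,
    compute_log_ratios,
    correct_isotope_impurities,
    default_design,
    filter_valid_sites,
    fit_normal_cutoffs,
    flag_significant,
    generate_dataset,
    normalize_loading,
    run_pipeline,
    summarize_hits,
)
from mitophos.phospho import TMT6_CHANNELS, intensity_column, make_impurity_matrix

ICOLS = [intensity_column(c) for c in TMT6_CHANNELS]


def site_rows(intensities, **extra):
    """Build a minimal site table from a list of 6-vectors."""
    n = len(intensities)
    base = {
        "site_id": [f"S{i}" for i in range(n)],
        "protein_id": extra.pop("protein_id", [f"P{i}" for i in range(n)]),
        "position": np.arange(1, n + 1),
        "residue": ["S"] * n,
        "localization_prob": extra.pop("localization_prob", [0.9] * n),
        "sequence_window": extra.pop("sequence_window", ["AAAAAAASPAAAAAA"] * n),
        "is_contaminant": extra.pop("is_contaminant", [False] * n),
        "is_reverse": extra.pop("is_reverse", [False] * n),
    }
    df = pd.DataFrame(base)
    arr = np.asarray(intensities, dtype=float)
    for j, c in enumerate(ICOLS):
        df[c] = arr[:, j]
    return df


def protein_rows(intensities, protein_ids=None):
    n = len(intensities)
    df = pd.DataFrame({
        "protein_id": protein_ids or [f"P{i}" for i in range(n)],
        "is_contaminant": [False] * n,
        "is_reverse": [False] * n,
    })
    arr = np.asarray(intensities, dtype=float)
    for j, c in enumerate(ICOLS):
        df[c] = arr[:, j]
    return df


class TestFilter:
    def test_flag_and_completeness_filter(self):
        sites = site_rows(np.full((4, 6), 100.0),
                          is_contaminant=[True, False, False, False],
                          is_reverse=[False, True, False, False])
        out = filter_valid_sites(sites)
        assert len(out) == 2

    def test_single_zero_intensity_removes_row(self):
        inten = np.full((3, 6), 50.0)
        inten[1, 4] = 0.0
        out = filter_valid_sites(site_rows(inten))
        assert list(out["site_id"]) == ["S0", "S2"]

    def test_counting_against_generator_truth(self):
        cfg = GeneratorConfig(n_sites=2000, n_proteins=300, frac_missing=0.1,
                              frac_contaminant=0.05, seed=5)
        sites, _, truth = generate_dataset(cfg)
        out = filter_valid_sites(sites)
        flagged = truth["is_contaminant"] | truth["is_reverse"]
        expected = int((~flagged & (truth["n_missing"] == 0)).sum())
        assert len(out) == expected


class TestImpurityCorrection:
    def test_identity_matrix_is_noop(self):
        sites = site_rows(np.random.default_rng(0).uniform(10, 100, (5, 6)))
        out = correct_isotope_impurities(sites, np.eye(6))
        assert np.allclose(out[ICOLS], sites[ICOLS])

    def test_recovers_forward_constructed_truth(self):
        rng = np.random.default_rng(1)
        true = rng.uniform(50, 500, (20, 6))
        m = make_impurity_matrix(6, spill=0.05)
        observed = true @ m.T
        out = correct_isotope_impurities(site_rows(observed), m)
        assert np.max(np.abs(out[ICOLS].to_numpy() - true)) <= 1e-9

    def test_singular_matrix_rejected(self):
        m = np.zeros((6, 6)); m[0, 0] = 1.0
        with pytest.raises(DataError, match="singular"):
            correct_isotope_impurities(site_rows(np.ones((2, 6))), m)

    def test_column_sum_checked(self):
        m = np.eye(6) * 1.2
        with pytest.raises(DataError, match="sum"):
            correct_isotope_impurities(site_rows(np.ones((2, 6))), m)


class TestNormalizeLoading:
    def test_equal_medians_identity_up_to_scale(self):
        sites = site_rows(np.full((4, 6), 80.0))
        proteins = protein_rows(np.full((5, 6), 40.0))
        s2, p2 = normalize_loading(sites, proteins)
        # equal input medians -> every channel divided by the same factor
        ratio = sites[ICOLS].to_numpy() / s2[ICOLS].to_numpy()
        assert np.allclose(ratio, ratio[0, 0])

    def test_channel_rescaling_invisible(self):
        rng = np.random.default_rng(2)
        sites = site_rows(rng.uniform(10, 100, (8, 6)))
        proteins = protein_rows(rng.uniform(10, 100, (9, 6)))
        s_ref, p_ref = normalize_loading(sites, proteins)
        scaled_s, scaled_p = sites.copy(), proteins.copy()
        scaled_s[ICOLS[3]] *= 2.0
        scaled_p[ICOLS[3]] *= 2.0
        s2, p2 = normalize_loading(scaled_s, scaled_p)
        assert np.max(np.abs(s2[ICOLS].to_numpy() - s_ref[ICOLS].to_numpy())) <= 1e-9
        assert np.max(np.abs(p2[ICOLS].to_numpy() - p_ref[ICOLS].to_numpy())) <= 1e-9

    def test_post_normalization_medians_equal(self):
        rng = np.random.default_rng(3)
        proteins = protein_rows(rng.lognormal(4, 1, (101, 6)))
        sites = site_rows(rng.lognormal(4, 1, (50, 6)))
        _, p2 = normalize_loading(sites, proteins)
        medians = p2[ICOLS].median(axis=0).to_numpy()
        assert np.max(np.abs(medians - medians[0])) < 1e-9 * medians[0]

    def test_zero_median_channel_rejected(self):
        proteins = protein_rows(np.zeros((5, 6)))
        with pytest.raises(DataError, match="median"):
            normalize_loading(site_rows(np.ones((2, 6))), proteins)


class TestLogRatios:
    def test_flat_intensities_give_zero_ratios(self):
        sites = site_rows([np.full(6, 30.0)])
        proteins = protein_rows([np.full(6, 60.0)])
        out = compute_log_ratios(sites, proteins, default_design())
        assert out["mean_log2_ratio"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert bool(out["protein_normalized"].iloc[0])

    def test_site_halved_in_treated(self):
        inten = np.array([[40, 40, 40, 20, 20, 20]], dtype=float)
        out = compute_log_ratios(site_rows(inten), protein_rows([np.full(6, 60.0)]),
                                 default_design())
        assert out["mean_log2_ratio"].iloc[0] == pytest.approx(-1.0, abs=1e-12)

    def test_protein_change_cancels(self):
        halved = np.array([[40, 40, 40, 20, 20, 20]], dtype=float)
        out = compute_log_ratios(site_rows(halved), protein_rows(halved),
                                 default_design())
        assert out["mean_log2_ratio"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_missing_protein_keeps_raw_ratio(self):
        inten = np.array([[40, 40, 40, 20, 20, 20]], dtype=float)
        sites = site_rows(inten, protein_id=["ORPHAN"])
        out = compute_log_ratios(sites, protein_rows([np.full(6, 60.0)]),
                                 default_design())
        assert not bool(out["protein_normalized"].iloc[0])
        assert out["mean_log2_ratio"].iloc[0] == pytest.approx(-1.0, abs=1e-12)

    def test_protein_shift_property(self):
        """Multiplying one protein's treated channels by 2**c shifts its
        sites' normalised ratios by exactly -c."""
        rng = np.random.default_rng(4)
        sites = site_rows(rng.uniform(20, 80, (3, 6)), protein_id=["P0"] * 3)
        prot = protein_rows(rng.uniform(20, 80, (1, 6)), protein_ids=["P0"])
        base = compute_log_ratios(sites, prot, default_design())
        shifted = prot.copy()
        for c in ICOLS[3:]:
            shifted[c] *= 2.0 ** 0.7
        out = compute_log_ratios(sites, shifted, default_design())
        diff = out["mean_log2_ratio"] - base["mean_log2_ratio"]
        assert np.allclose(diff, -0.7, atol=1e-12)


class TestCutoffs:
    def test_standard_normal_sample(self):
        # constructed to have sample mean 0 and sample sd exactly 1
        x = np.arange(-5.0, 6.0)
        x = x / np.std(x, ddof=1)
        cm = fit_normal_cutoffs(x)
        assert cm.mean == pytest.approx(0.0, abs=1e-12)
        assert cm.sd == pytest.approx(1.0, abs=1e-12)
        assert cm.lo == pytest.approx(-1.96) and cm.hi == pytest.approx(1.96)

    def test_degenerate_distribution_rejected(self):
        with pytest.raises(DataError, match="degenerate"):
            fit_normal_cutoffs(np.full(50, 0.3))

    def test_too_few_values_rejected(self):
        with pytest.raises(DataError, match="10"):
            fit_normal_cutoffs(np.arange(5.0))

    def test_recovers_sampling_distribution(self):
        rng = np.random.default_rng(123)
        n = 10_000
        x = rng.normal(0.2, 0.5, n)
        cm = fit_normal_cutoffs(x)
        se_mean = 0.5 / np.sqrt(n)
        se_sd = 0.5 / np.sqrt(2 * (n - 1))
        assert abs(cm.mean - 0.2) < 3 * se_mean
        assert abs(cm.sd - 0.5) < 3 * se_sd


class TestFlagging:
    def make_results(self, means):
        return pd.DataFrame({
            "site_id": [f"S{i}" for i in range(len(means))],
            "protein_id": [f"P{i}" for i in range(len(means))],
            "mean_log2_ratio": means,
        })

    def test_boundary_is_not_significant(self):
        cm = CutoffModel(mean=0.0, sd=1.0)
        out = flag_significant(self.make_results([cm.lo, cm.lo - 0.01, cm.hi, cm.hi + 0.01]), cm)
        assert list(out["significant"]) == [False, True, False, True]
        assert list(out["direction"]) == ["none", "down", "none", "up"]

    def test_negation_swaps_directions(self):
        rng = np.random.default_rng(6)
        means = rng.normal(0, 1.5, 500)
        cm = CutoffModel(mean=0.0, sd=1.0)
        fwd = flag_significant(self.make_results(means), cm)
        rev = flag_significant(self.make_results(-means), cm)
        assert (fwd["direction"] == "down").sum() == (rev["direction"] == "up").sum()
        assert (fwd["direction"] == "up").sum() == (rev["direction"] == "down").sum()
        assert list(fwd["significant"]) == list(rev["significant"])


class TestMotif:
    @pytest.mark.parametrize("window,expected", [
        ("AAAAAAASPAAAAAA", True),
        ("AAAAAAATPAAAAAA", True),
        ("AAAAAAASAAAAAAA", False),
        ("AAAAAAAYPAAAAAA", False),
        ("PPPPPPPSKPPPPPP", False),
    ])
    def test_examples(self, window, expected):
        assert annotate_stp_motif(window) is expected

    def test_even_window_rejected(self):
        with pytest.raises(DataError, match="odd"):
            annotate_stp_motif("AASPAA")

    def test_planted_motif_fraction_recovered(self):
        cfg = GeneratorConfig(n_sites=5000, frac_stp=0.4, seed=9)
        sites, _, truth = generate_dataset(cfg)
        found = np.array([annotate_stp_motif(w) for w in sites["sequence_window"]])
        assert np.array_equal(found, truth["is_stp"].to_numpy())
        # binomial 99% bound around the configured fraction
        se = np.sqrt(0.4 * 0.6 / 5000)
        assert abs(found.mean() - 0.4) < 2.58 * se


class TestSummary:
    def test_empty_table(self):
        out = summarize_hits(pd.DataFrame(columns=["site_id"]))
        assert out == dict(n_quantified=0, n_stp=0, n_significant_down=0,
                           n_proteins_down=0, n_class1=0)

    def test_counts_sites_and_distinct_proteins(self):
        df = pd.DataFrame({
            "site_id": ["a", "b", "c", "d"],
            "protein_id": ["P1", "P1", "P2", "P3"],
            "mean_log2_ratio": [-2.0, -2.0, -2.0, -0.2],
            "significant": [True, True, True, False],
            "direction": ["down", "down", "down", "none"],
            "is_stp_motif": [True, False, True, True],
            "is_class1": [True, True, False, True],
        })
        out = summarize_hits(df, fold_threshold=4.0)
        assert out["n_significant_down"] == 3
        assert out["n_proteins_down"] == 2
        assert out["n_stp"] == 2  # motif count restricted to class-I sites
        assert out["n_class1"] == 3

    def test_fold_threshold_applies(self):
        df = pd.DataFrame({
            "site_id": ["a"], "protein_id": ["P1"], "mean_log2_ratio": [-0.8],
            "significant": [True], "direction": ["down"],
            "is_stp_motif": [False], "is_class1": [True],
        })
        # significant but above the 2-fold reporting threshold
        assert summarize_hits(df, fold_threshold=2.0)["n_significant_down"] == 0


class TestEndToEnd:
    def test_channel_scale_invariance(self, small_dataset):
        sites, proteins, _ = small_dataset
        ref, _, _ = run_pipeline(sites, proteins)
        for ch in (0, 5):
            s2, p2 = sites.copy(), proteins.copy()
            s2[ICOLS[ch]] *= 7.3
            p2[ICOLS[ch]] *= 7.3
            out, _, _ = run_pipeline(s2, p2)
            assert np.max(np.abs(out["mean_log2_ratio"].to_numpy()
                                 - ref["mean_log2_ratio"].to_numpy())) <= 1e-9
            assert list(out["significant"]) == list(ref["significant"])
            assert list(out["direction"]) == list(ref["direction"])

    def test_row_order_invariance(self, small_dataset):
        sites, proteins, _ = small_dataset
        ref, _, summary_ref = run_pipeline(sites, proteins)
        shuffled = sites.sample(frac=1.0, random_state=0).reset_index(drop=True)
        out, _, summary = run_pipeline(shuffled, proteins)
        assert summary == summary_ref
        merged = ref.merge(out, on="site_id", suffixes=("_a", "_b"))
        assert np.allclose(merged["mean_log2_ratio_a"], merged["mean_log2_ratio_b"])
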