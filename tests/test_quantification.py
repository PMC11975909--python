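"""Well summaries, paired-feature normalization, DMSO-relative effects,
and slope/association analyses."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from phenoscreen import quantification as quant
from phenoscreen import synthetic as syn
from conftest import make_layout_row


def _labels(small=0, large=0, annexin=0, frag=0, ac=0, ad=0, pod=0,
            nopod=0, phago=0, largeplain=0):
    """Construct a per-cell label frame with the given bin counts."""
    n = small + large
    rows = []
    for i in range(n):
        size = "small_round" if i < small else "large_round"
        rows.append({"size_class": size, "annexin": "annexin_neg",
                     "fragment": "intact", "actin": pd.NA,
                     "podosome": pd.NA, "phago": pd.NA})
    df = pd.DataFrame(rows, columns=["size_class", "annexin", "fragment",
                                     "actin", "podosome", "phago"])
    if annexin:
        df.loc[: annexin - 1, "annexin"] = "annexin_pos"
    if frag:
        df.loc[: frag - 1, "fragment"] = "fragmented"
    small_idx = df.index[df["size_class"] == "small_round"]
    df.loc[small_idx[:ac], "actin"] = "contracted"
    df.loc[small_idx[ac:ac + ad], "actin"] = "dispersed"
    large_idx = df.index[df["size_class"] == "large_round"]
    df.loc[large_idx[:pod], "podosome"] = "podosome_pos"
    df.loc[large_idx[pod:pod + nopod], "podosome"] = "podosome_neg"
    df.loc[large_idx[:phago], "phago"] = "phagocytosis"
    df.loc[large_idx[phago:phago + largeplain], "phago"] = "large_round"
    return df


class TestSummarizeWell:
    def test_simple_size_fractions(self):
        s = quant.summarize_well(_labels(small=70, large=30))
        assert s["frac_small"] == pytest.approx(0.7)
        assert s["frac_large"] == pytest.approx(0.3)
        assert s["n_cells"] == 100

    def test_empty_well_flagged_undefined(self):
        s = quant.summarize_well(_labels())
        assert s["n_cells"] == 0
        assert np.isnan(s["frac_small"])
        assert np.isnan(s["frac_annexin"])

    def test_unknown_label_rejected(self):
        df = _labels(small=2)
        df.loc[0, "actin"] = "wiggly"
        with pytest.raises(quant.LabelVocabularyError, match="wiggly"):
            quant.summarize_well(df)

    def test_truth_labels_reproduce_truth_fractions_exactly(self):
        """Identity pipeline: generator truth -> labels -> summary."""
        truth = syn.simulate_well(make_layout_row(), syn.EffectSpec(), 300,
                                  seed=61)
        labels = quant.labels_from_truth(truth.cells)
        s = quant.summarize_well(labels)
        fr = truth.realized_fractions()
        assert s["frac_small"] == pytest.approx(fr["small_round"])
        assert s["frac_annexin"] == pytest.approx(fr["annexin_pos"])
        assert s["frac_fragmented"] == pytest.approx(fr["fragmented_nucleus"])
        assert s["frac_actin_contracted"] == pytest.approx(fr["actin_contracted"])
        assert s["frac_podosome"] == pytest.approx(fr["podosome_pos"])
        assert s["frac_phagocytosis"] == pytest.approx(fr["phagocytosis"])


class TestNormalize:
    def test_phagocytosis_norm_formula(self):
        s = quant.summarize_well(_labels(small=0, large=40, phago=10,
                                         largeplain=30))
        n = quant.normalize(s)
        assert n["phagocytosis_norm"] == pytest.approx(10 / (10 + 30))

    def test_actin_contracted_zero_dispersed_five(self):
        s = quant.summarize_well(_labels(small=10, ac=0, ad=5))
        n = quant.normalize(s)
        assert n["actin_contracted_norm"] == pytest.approx(0.0)
        assert n["actin_dispersed_norm"] == pytest.approx(1.0)

    def test_zero_denominator_flags_undefined(self):
        s = quant.summarize_well(_labels(small=5, large=3))
        n = quant.normalize(s)
        assert np.isnan(n["podosome_norm"])
        assert np.isnan(n["no_podosome_norm"])

    def test_complementary_pairs_sum_to_one_where_defined(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            s = quant.summarize_well(_labels(
                small=int(rng.integers(1, 30)), large=int(rng.integers(1, 30)),
                ac=int(rng.integers(0, 5)), ad=int(rng.integers(0, 5)),
                pod=int(rng.integers(0, 5)), nopod=int(rng.integers(0, 5))))
            n = quant.normalize(s)
            for a, b in (("actin_contracted_norm", "actin_dispersed_norm"),
                         ("podosome_norm", "no_podosome_norm")):
                if not np.isnan(n[a]):
                    assert n[a] + n[b] == pytest.approx(1.0)
                    assert 0.0 <= n[a] <= 1.0


def _summaries_for_effects(n_donors=30, fold=2.0, seed=0):
    """Truth-label summaries with an injected annexin fold (no imaging)."""
    spec = syn.EffectSpec(
        baseline=syn.PhenotypeBaseline(annexin=0.1),
        effects={("TLR8", 24.0): syn.ConditionEffect(annexin_fold=fold)},
        donor_sd=0.15, donor_seed=seed)
    frames = []
    for d in range(n_donors):
        for cond in ("DMSO", "TLR8"):
            for rep in range(3):
                row = make_layout_row(condition=cond, donor=f"d{d:02d}",
                                      plate=f"P{d:02d}",
                                      well=f"{'AB'[cond == 'TLR8']}{rep:02d}")
                truth = syn.simulate_well(row, spec, 400,
                                          seed=seed * 7919 + d * 101 +
                                          rep * 7 + (cond == "TLR8"))
                labels = quant.labels_from_truth(truth.cells)
                frames.append(labels)
    return quant.summarize_wells(pd.concat(frames, ignore_index=True))


class TestEffectVsControl:
    def test_wells_identical_to_control_give_delta_zero_fold_one(self):
        df = _summaries_for_effects(n_donors=3, fold=1.0)
        per_well, _ = quant.effect_vs_control(df, features=["frac_small"])
        dmso = per_well[per_well["condition"] == "DMSO"]
        # control wells measured against their own stratum mean scatter
        # around 0/1, and the stratum mean maps to exactly 0/1
        stratum_mean = dmso.groupby(["plate_id"])["delta"].mean()
        np.testing.assert_allclose(stratum_mean, 0.0, atol=1e-12)

    def test_injected_annexin_fold_recovered_within_10pct(self):
        df = _summaries_for_effects(n_donors=30, fold=2.0)
        _, est = quant.effect_vs_control(df, features=["frac_annexin"])
        sel = est[(est["condition"] == "TLR8") & (est["feature"] == "frac_annexin")]
        assert abs(sel["median_fold"].iloc[0] - 2.0) / 2.0 < 0.10

    def test_stratum_without_control_skipped_with_warning(self):
        df = _summaries_for_effects(n_donors=2, fold=1.5)
        df = df[~((df["plate_id"] == "P00") & (df["condition"] == "DMSO"))]
        with pytest.warns(UserWarning, match="no DMSO"):
            per_well, _ = quant.effect_vs_control(df, features=["frac_small"])
        assert not (per_well["plate_id"] == "P00").any()

    def test_control_only_stratum_contributes_no_effect_rows(self):
        df = _summaries_for_effects(n_donors=2, fold=1.0)
        df = df[df["condition"] == "DMSO"]
        _, est = quant.effect_vs_control(df, features=["frac_small"])
        assert est.empty


class TestAssociate:
    def test_exact_linear_relation_recovers_printed_slope(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(-0.5, 0.5, 50)
        y = 0.03142 * x
        res = quant.associate(x, y)
        assert res.slope == pytest.approx(0.03142)
        assert res.rho == pytest.approx(1.0)

    def test_constant_y_gives_zero_slope_undefined_rho(self):
        x = np.arange(10.0)
        res = quant.associate(x, np.ones(10))
        assert res.slope == pytest.approx(0.0)
        assert res.undefined and np.isnan(res.rho)

    def test_constant_x_flags_slope_undefined(self):
        res = quant.associate(np.ones(5), np.arange(5.0))
        assert res.undefined and np.isnan(res.slope)

    def test_rho_matches_rank_correlation_oracle_small_n(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            x = rng.normal(0, 1, 8)
            y = rng.normal(0, 1, 8)
            res = quant.associate(x, y)
            rho_oracle = np.corrcoef(rankdata(x), rankdata(y))[0, 1]
            assert res.rho == pytest.approx(rho_oracle)

    @pytest.mark.parametrize("slope", [0.03142, -0.08836])
    def test_generator_coupling_slope_recovered_within_10pct(self, slope):
        """End-to-end slope recovery at the extreme printed magnitudes."""
        from phenoscreen.pipeline import slope_recovery_experiment

        fit = slope_recovery_experiment(slope, seed=0, n_wells=200,
                                        noise_sd=0.01)
        assert abs(fit - slope) / abs(slope) < 0.10

    def test_associate_deltas_pivots_per_well(self):
        per_well = pd.DataFrame({
            "plate_id": ["P1"] * 6, "donor_id": ["d"] * 6,
            "timepoint_h": [24.0] * 6,
            "well_id": ["A", "A", "B", "B", "C", "C"],
            "condition": ["T"] * 6,
            "feature": ["x", "y"] * 3,
            "delta": [0.1, 0.2, 0.2, 0.4, 0.3, 0.6],
        })
        res = quant.associate_deltas(per_well, "x", "y")
        assert res.slope == pytest.approx(2.0)
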