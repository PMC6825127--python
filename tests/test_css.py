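import numpy as np
import pandas as pd
import pytest

from germline_nog.css import (
    CSSClassifier,
    CSSModel,
    _call_from_votes,
    calls_to_frame,
    classify_expression,
    classify_one,
    fit_css,
    predict,
)
from germline_nog.mss import NOGSignature


def toy_signature(genes=("A", "B", "C", "D"), low=(1.0, 2.0, 3.0, 4.0),
                  high=(4.0, 3.0, 2.0, 1.0), name="H"):
    genes = list(genes)
    return NOGSignature(
        hallmark=name, genes=genes,
        centroid_low=pd.Series(low, index=genes),
        centroid_high=pd.Series(high, index=genes),
    )


class TestClassifyOne:
    def test_profile_equal_to_high_centroid(self):
        sig = toy_signature()
        assert classify_one(sig.centroid_high, sig) == "high"
        assert classify_one(sig.centroid_low, sig) == "low"

    def test_exact_tie_goes_low(self):
        # palindromic profile against mirrored centroids: r_low == r_high == 0
        sig = toy_signature(low=(1.0, 2.0, 3.0, 4.0), high=(4.0, 3.0, 2.0, 1.0))
        profile = pd.Series([1.0, 2.0, 2.0, 1.0], index=list("ABCD"))
        assert classify_one(profile, sig) == "low"

    def test_hand_computed_pearson(self):
        # r(profile, low) and r(profile, high) computed by the textbook formula
        sig = toy_signature(low=(1.0, 2.0, 3.0, 4.0), high=(2.0, 1.0, 4.0, 3.0))
        profile = pd.Series([1.5, 1.0, 4.5, 3.0], index=list("ABCD"))

        def pearson(x, y):
            x, y = np.asarray(x, float), np.asarray(y, float)
            xc, yc = x - x.mean(), y - y.mean()
            return (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))

        r_low = pearson(profile, sig.centroid_low)
        r_high = pearson(profile, sig.centroid_high)
        assert r_high > r_low
        assert classify_one(profile, sig) == "high"

    def test_scale_invariance(self, rng):
        sig = toy_signature()
        profile = pd.Series(rng.random(4), index=list("ABCD"))
        base = classify_one(profile, sig)
        assert classify_one(3.7 * profile + 11.0, sig) == base

    def test_zero_variance_abstains(self):
        sig = toy_signature()
        flat = pd.Series([2.0] * 4, index=list("ABCD"))
        assert classify_one(flat, sig) == "abstain"

    def test_majority_genes_missing_abstains(self):
        sig = toy_signature()
        partial = pd.Series([1.0], index=["A"])
        assert classify_one(partial, sig) == "abstain"


class TestVoteBand:
    @pytest.mark.parametrize(
        "k,s_eff,K_low,K_high,expected",
        [
            (0, 3, 2, 3, "low"),
            (2, 3, 2, 3, "low"),
            (3, 3, 2, 3, "high"),
            (1, 3, 0, 3, "unpredicted"),
            (0, 0, 0, 1, "unpredicted"),   # all abstained
        ],
    )
    def test_band_semantics(self, k, s_eff, K_low, K_high, expected):
        assert _call_from_votes(k, s_eff, 3, K_low, K_high) == expected

    def test_abstention_rescales_cutoffs_half_down(self):
        # S=10, K_low=4, K_high=8; with s_eff=5 the cutoffs become 2 and 4
        assert _call_from_votes(2, 5, 10, 4, 8) == "low"
        assert _call_from_votes(3, 5, 10, 4, 8) == "unpredicted"
        assert _call_from_votes(4, 5, 10, 4, 8) == "high"
        # ties round down: 5*5/10 = 2.5 -> 2
        assert _call_from_votes(2, 5, 10, 5, 8) == "low"


def separable_fixture(n_sig=4, n_per_class=10):
    """Profiles identical to a centroid, so votes are unanimous."""
    sigs, profiles, labels = [], {}, {}
    genes_all = []
    for i in range(n_sig):
        genes = [f"G{i}_{j}" for j in range(4)]
        genes_all += genes
        sigs.append(toy_signature(genes=genes, name=f"H{i}"))
    for s in range(n_per_class):
        lo = pd.concat([sig.centroid_low for sig in sigs])
        hi = pd.concat([sig.centroid_high for sig in sigs])
        profiles[f"L{s}"], labels[f"L{s}"] = lo, "non-recurred"
        profiles[f"H{s}"], labels[f"H{s}"] = hi, "recurred"
    return sigs, pd.DataFrame(profiles), pd.Series(labels)


class TestFitCSS:
    def test_separable_votes_reach_perfect_accuracy(self):
        sigs, profiles, labels = separable_fixture()
        model = fit_css(sigs, profiles, labels)
        feasible = model.fit_report[model.fit_report.feasible]
        assert model.K_low == 0 and model.K_high == len(sigs)
        row = feasible[(feasible.K_low == model.K_low)
                       & (feasible.K_high == model.K_high)].iloc[0]
        assert row.low_accuracy == 100.0 and row.high_accuracy == 100.0

    def test_grid_size_for_three_signatures(self):
        sigs, profiles, labels = separable_fixture(n_sig=3)
        model = fit_css(sigs, profiles, labels)
        assert len(model.fit_report) == 6  # C(4, 2) pairs with K_low < K_high

    def test_uninformative_votes_near_base_rates(self, rng):
        """Profiles carrying no label signal: no cutoff pair should beat the
        class base rates by a wide margin on average."""
        sigs, _, _ = separable_fixture(n_sig=3)
        genes = [g for sig in sigs for g in sig.genes]
        samples = [f"S{i}" for i in range(60)]
        profiles = pd.DataFrame(rng.random((len(genes), 60)), index=genes,
                                columns=samples)
        labels = pd.Series(["recurred" if i < 30 else "non-recurred"
                            for i in range(60)], index=samples)
        model = fit_css(sigs, profiles, labels, coverage_floor=0.3)
        feas = model.fit_report[model.fit_report.feasible]
        acc = feas[["low_accuracy", "high_accuracy"]].mean(axis=1).dropna()
        assert acc.mean() < 75.0  # base rate 50; sampling noise allowed

    def test_missing_labels_rejected(self):
        sigs, profiles, labels = separable_fixture()
        with pytest.raises(ValueError):
            fit_css(sigs, profiles, labels.iloc[:3])


class TestPredict:
    def test_calls_and_frame(self):
        sigs, profiles, labels = separable_fixture()
        model = fit_css(sigs, profiles, labels)
        calls = predict(model, profiles)
        frame = calls_to_frame(calls)
        y = labels[frame.index]
        assert (frame.loc[y == "recurred", "call"] == "high").all()
        assert (frame.loc[y == "non-recurred", "call"] == "low").all()
        assert frame["votes_high"].between(0, len(sigs)).all()

    def test_unpredicted_band(self):
        sigs, profiles, labels = separable_fixture(n_sig=4)
        model = CSSModel(signatures=sigs, K_low=0, K_high=4)
        mixed = pd.concat([sigs[0].centroid_high, sigs[1].centroid_high,
                           sigs[2].centroid_low, sigs[3].centroid_low])
        calls = predict(model, mixed.to_frame("SX"))
        assert calls[0].votes_high == 2
        assert calls[0].call == "unpredicted"


class TestExpressionClassification:
    def test_expression_matching_high_group_called_high(self, rng):
        sigs, _, _ = separable_fixture(n_sig=3)
        genes = [g for sig in sigs for g in sig.genes]
        # training expression: two clusters; validation sample near cluster "high"
        lo = rng.normal(0.0, 0.05, (len(genes), 8))
        hi = rng.normal(1.0, 0.05, (len(genes), 8)) * np.linspace(
            0.5, 1.5, len(genes))[:, None]
        val = hi.mean(axis=1, keepdims=True)
        expr = pd.DataFrame(np.hstack([lo, hi, val]), index=genes,
                            columns=[f"L{i}" for i in range(8)]
                            + [f"H{i}" for i in range(8)] + ["V0"])
        labels = pd.Series({**{f"L{i}": "non-recurred" for i in range(8)},
                            **{f"H{i}": "recurred" for i in range(8)}})
        model = CSSModel(signatures=sigs, K_low=0, K_high=3)
        calls = {c.sample_id: c for c in classify_expression(model, expr, labels)}
        assert calls["V0"].call == "high"
        assert calls["V0"].votes_high == 3

    def test_matrix_without_signature_genes_abstains_everywhere(self, rng):
        sigs, _, _ = separable_fixture(n_sig=2)
        expr = pd.DataFrame(rng.random((5, 6)),
                            index=[f"X{i}" for i in range(5)],
                            columns=[f"S{i}" for i in range(6)])
        labels = pd.Series({"S0": "non-recurred", "S1": "recurred",
                            "S2": "non-recurred", "S3": "recurred"})
        model = CSSModel(signatures=sigs, K_low=0, K_high=2)
        calls = classify_expression(model, expr, labels)
        assert all(c.n_effective == 0 and c.call == "unpredicted" for c in calls)

    def test_loo_keeps_correct_call_without_self_match(self):
        # two clear per-gene patterns; under LOO a training sample's centroid
        # is rebuilt from its class sibling only, and the call must survive
        sigs, _, _ = separable_fixture(n_sig=1)
        genes = sigs[0].genes
        expr = pd.DataFrame(
            {"A1": [0.0, 1.0, 2.0, 3.0], "A2": [0.1, 1.1, 1.9, 3.0],
             "B1": [3.0, 2.1, 1.0, 0.1], "B2": [2.9, 2.0, 1.1, 0.0]},
            index=genes)
        labels = pd.Series({"A1": "non-recurred", "A2": "non-recurred",
                            "B1": "recurred", "B2": "recurred"})
        model = CSSModel(signatures=sigs, K_low=0, K_high=1)
        for mode in ("loo", "plain"):
            calls = {c.sample_id: c
                     for c in classify_expression(model, expr, labels, mode=mode)}
            assert calls["B1"].call == "high" and calls["A1"].call == "low", mode


class TestEstimator:
    def test_sklearn_fit_predict(self):
        sigs, profiles, labels = separable_fixture()
        clf = CSSClassifier(signatures=sigs).fit(profiles.T, labels.values)
        assert clf.K_low_ == 0 and clf.K_high_ == len(sigs)
        pred = clf.predict(profiles.T)
        assert set(pred) <= {"low", "high", "unpredicted"}
        assert (pred == np.where(labels.values == "recurred", "high", "low")).all()
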