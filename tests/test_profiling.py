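"""Liability profiling: mapping, applicability domain, concern scores."""

import numpy as np
import pytest

from liabprof.featurization import featurize, similarity_matrix_from_smiles, tanimoto
from liabprof.modeling import fit_model
from liabprof.profiling import (
    LIABILITY_GROUPS,
    LiabilityMapping,
    assess_ad,
    classify_concern,
    liability_scores,
    load_default_mapping,
    profile_compounds,
    two_sigma_cutoff,
)


@pytest.fixture(scope="module")
def mapping():
    return load_default_mapping()


class TestMapping:
    def test_seven_groups(self, mapping):
        assert set(mapping.groups) == set(LIABILITY_GROUPS)

    def test_reference_group_sizes(self, mapping):
        sizes = {g: len(ts) for g, ts in mapping.groups.items()}
        assert sizes == {"CV": 24, "CNS": 19, "GI": 13, "ED": 7, "PU": 5, "RE": 2, "IM": 6}

    def test_targets_shared_across_groups(self, mapping):
        assert "DRD2" in mapping.groups["CV"]
        assert "DRD2" in mapping.groups["CNS"]
        assert "DRD2" in mapping.groups["ED"]

    def test_malformed_mapping_rejected(self):
        with pytest.raises(ValueError):
            LiabilityMapping({"CV": ("KCNH2",)})


class TestConcern:
    @pytest.mark.parametrize("p,expected", [(7.2, "C"), (5.0, "nC"), (6.5, "C"), (6.49, "nC")])
    def test_cutoff_convention(self, p, expected):
        assert classify_concern(p) == expected

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            classify_concern(float("nan"))

    def test_two_sigma_variable_cutoff(self, rng):
        y = rng.normal(6.0, 0.5, size=500)
        cut = two_sigma_cutoff(y)
        assert cut == pytest.approx(y.mean() + 2 * y.std(ddof=1))


class TestLiabilityScores:
    def test_extremes(self, mapping):
        all_c = {t: "C" for t in mapping.targets}
        scores, _ = liability_scores(all_c, mapping)
        assert set(scores.values()) == {1.0}
        none_c = {t: "nC" for t in mapping.targets}
        scores, _ = liability_scores(none_c, mapping)
        assert set(scores.values()) == {0.0}

    def test_direct_ratio(self):
        m = LiabilityMapping({
            "CV": ("A", "B", "C", "D", "E"), "CNS": ("A",), "GI": ("B",),
            "ED": ("C",), "PU": ("D",), "RE": ("E",), "IM": ("A", "B"),
        })
        flags = {"A": "C", "B": "C", "C": "nC", "D": "nC", "E": "nC"}
        scores, counts = liability_scores(flags, m)
        assert scores["CV"] == pytest.approx(0.4)  # 2 of 5
        assert counts["CV"] == (2, 3)
        assert scores["IM"] == 1.0

    def test_counting_oracle_random_flags(self, mapping, rng):
        for _ in range(10):
            flags = {t: ("C" if rng.random() < 0.5 else "nC") for t in mapping.targets}
            scores, counts = liability_scores(flags, mapping)
            for g, ts in mapping.groups.items():
                c = sum(1 for t in ts if flags[t] == "C")
                assert counts[g] == (c, len(ts) - c)
                assert scores[g] == pytest.approx(c / len(ts))
                assert 0.0 <= scores[g] <= 1.0

    def test_monotone_in_concern_flags(self, mapping):
        targets = mapping.groups["CV"]
        flags = {t: "nC" for t in mapping.targets}
        prev = -1.0
        for t in targets:
            flags[t] = "C"
            score = liability_scores(flags, mapping)[0]["CV"]
            assert score >= prev
            prev = score

    def test_missing_flag_names_target(self, mapping):
        flags = {t: "C" for t in mapping.targets if t != "KCNH2"}
        with pytest.raises(KeyError, match="KCNH2"):
            liability_scores(flags, mapping)


@pytest.fixture(scope="module")
def toy_registry(library100, panel100):
    clean, _ = panel100
    df = clean["T1"]
    from liabprof.featurization import build_feature_matrix

    X, _ = build_feature_matrix(df["smiles"].tolist())
    fps = similarity_matrix_from_smiles(df["smiles"].tolist())
    cfg = {"n_estimators": 30, "max_depth": 3}
    model = fit_model(X, df["pACTIVITY"].to_numpy(), "gb", cfg, 0, fingerprints=fps)
    # spans all seven liability groups
    return {t: model for t in ("KCNH2", "DRD2", "ACHE", "AVPR1A", "PTGS2")}


class TestApplicabilityDomain:
    def test_training_compound_is_in_domain(self, library100, toy_registry):
        tc, fulfilled = assess_ad(featurize(library100[0]), toy_registry["KCNH2"])
        assert tc == 1.0 and fulfilled

    def test_matches_bruteforce_pairwise_oracle(self, toy_registry, library100):
        model = toy_registry["KCNH2"]
        query = featurize("c1ccc2nc(NCCO)ccc2c1")
        expected = max(tanimoto(query.similarity_bits, row)
                       for row in model.fingerprint_store_)
        tc, _ = assess_ad(query, model)
        assert tc == pytest.approx(expected)

    def test_threshold_is_strict(self, toy_registry, library100):
        model = toy_registry["KCNH2"]
        query = featurize(library100[3])
        tc, fulfilled = assess_ad(query, model, threshold=1.0)
        assert tc == 1.0 and not fulfilled  # Tc must strictly exceed

    def test_empty_store_rejected(self):
        class Bare:
            fingerprint_store_ = np.empty((0, 2048))

        with pytest.raises(ValueError):
            assess_ad(featurize("CCO"), Bare())


class TestProfileBatch:
    def test_batch_profile_contract(self, library100, toy_registry):
        profiles = profile_compounds([library100[0], "((bad", library100[1]], toy_registry)
        assert len(profiles) == 3
        assert profiles[1].error is not None
        ok = profiles[0]
        assert set(ok.predictions) == set(toy_registry)
        assert set(ok.scores) == set(LIABILITY_GROUPS)
        assert 0.0 <= ok.ad.overall_score <= 1.0
        # AD overall equals the fulfilled fraction (counting oracle)
        assert ok.ad.overall_score == pytest.approx(
            sum(ok.ad.fulfilled.values()) / len(ok.ad.fulfilled))

    def test_profile_invariant_to_registry_order(self, library100, toy_registry):
        rev = dict(reversed(list(toy_registry.items())))
        a = profile_compounds([library100[2]], toy_registry)[0]
        b = profile_compounds([library100[2]], rev)[0]
        assert a.scores == b.scores and a.predictions == b.predictions

    def test_empty_registry_rejected(self):
        with pytest.raises(ValueError):
            profile_compounds(["CCO"], {})
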