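import itertools

import numpy as np
import pandas as pd
import pytest

from crossomics.errors import ConfigError, DataError
from crossomics.metabolomics import (
    MetaboliteProfile,
    cluster_profiles,
    evaluate_predictions,
    hydrolysis_partition,
    load_chemotype_rules,
    load_compound_annotations,
    load_hydrolysis_table,
    predict_chemotype,
    to_proportions,
)


def ward_bruteforce(X: np.ndarray, labels):
    """Exhaustive Ward agglomeration by explicit within-cluster sum of squares.

    At each step merge the pair whose merge increases the total ESS least;
    heights are sqrt(2 * deltaESS) to match the scipy convention. Ties break
    on the lexicographically smallest member pair.
    """

    def ess(idx):
        pts = X[list(idx)]
        return ((pts - pts.mean(axis=0)) ** 2).sum()

    clusters = {i: frozenset([i]) for i in range(len(X))}
    next_id = len(X)
    merges = []
    while len(clusters) > 1:
        best = None
        for (ia, ca), (ib, cb) in itertools.combinations(sorted(clusters.items()), 2):
            delta = ess(ca | cb) - ess(ca) - ess(cb)
            key = (delta, tuple(sorted(ca | cb)))
            if best is None or key < best[0]:
                best = (key, ia, ib)
        (delta, _), ia, ib = best
        merges.append((clusters[ia] | clusters[ib], np.sqrt(2 * max(delta, 0.0))))
        clusters[next_id] = clusters.pop(ia) | clusters.pop(ib)
        next_id += 1
    return merges


class TestProportions:
    @pytest.mark.parametrize(
        "conc, want",
        [
            ([[5.0]], [[1.0]]),
            ([[2.0], [2.0]], [[0.5], [0.5]]),
            ([[1.0], [2.0], [3.0], [4.0]], [[0.1], [0.2], [0.3], [0.4]]),
        ],
    )
    def test_hand_division(self, conc, want):
        got = to_proportions(pd.DataFrame(conc, columns=["s1"]))
        np.testing.assert_allclose(got.to_numpy(), want)

    def test_zero_total_sample_dropped(self):
        df = pd.DataFrame({"s1": [1.0, 1.0], "s2": [0.0, 0.0]})
        with pytest.warns(UserWarning):
            got = to_proportions(df)
        assert list(got.columns) == ["s1"]

    def test_negative_rejected(self):
        with pytest.raises(DataError):
            to_proportions(pd.DataFrame({"s1": [-1.0, 2.0]}))

    def test_columns_sum_to_one(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.random((14, 20)))
        np.testing.assert_allclose(to_proportions(df).sum(axis=0), 1.0, atol=1e-12)


class TestClusterProfiles:
    def test_identical_samples_merge_at_zero(self):
        df = pd.DataFrame({"a": [0.5, 0.5], "b": [0.5, 0.5], "c": [0.9, 0.1]})
        tree = cluster_profiles(df)
        assert tree.linkage[0, 2] == pytest.approx(0.0)
        assert sorted(tree.linkage[0, :2]) == [0, 1]  # a and b first

    def test_closest_pair_merges_first(self):
        # d(AB)=1, d(AC)=d(BC)=10 -> Ward merges A,B first
        df = pd.DataFrame({"A": [0.0], "B": [1.0], "C": [10.0]})
        tree = cluster_profiles(df)
        assert sorted(tree.linkage[0, :2]) == [0, 1]

    def test_duplicate_sample_ids_rejected(self):
        df = pd.DataFrame([[0.1, 0.2], [0.9, 0.8]], columns=["a", "a"])
        with pytest.raises(DataError):
            cluster_profiles(df)

    def test_single_sample_rejected(self):
        with pytest.raises(DataError):
            cluster_profiles(pd.DataFrame({"a": [1.0]}))

    @pytest.mark.parametrize("n_samples", [2, 3, 4, 5, 6])
    def test_matches_bruteforce_ward(self, n_samples):
        """scipy's Ward linkage equals the explicit ESS agglomeration on
        every small continuous (tie-free) dataset we throw at it."""
        rng = np.random.default_rng(100 + n_samples)
        for _ in range(6):
            X = rng.random((n_samples, 4))
            df = pd.DataFrame(X.T, columns=[f"s{i}" for i in range(n_samples)])
            tree = cluster_profiles(df)
            expected = ward_bruteforce(X, df.columns)
            # compare the sets of merged leaves and the merge heights, in order
            from scipy.cluster import hierarchy

            members = {i: {i} for i in range(n_samples)}
            for row_idx, (li, ri, height, _) in enumerate(tree.linkage):
                merged = members[int(li)] | members[int(ri)]
                members[n_samples + row_idx] = merged
                exp_members, exp_height = expected[row_idx]
                assert merged == set(exp_members)
                assert height == pytest.approx(exp_height, abs=1e-8)

    def test_newick_roundtrip_labels(self):
        df = pd.DataFrame(
            np.random.default_rng(1).random((3, 4)), columns=["s1", "s2", "s3", "s4"]
        ).T
        df = pd.DataFrame(df.T.to_numpy(), columns=["s1", "s2", "s3", "s4"])
        nwk = cluster_profiles(df).to_newick()
        assert nwk.endswith(";")
        for label in df.columns:
            assert label in nwk


class TestHydrolysisPartition:
    def test_printed_percentages(self):
        """Worked rows of the bundled table: goitrin 12.4% (NZ) and 60.7% (CH)."""
        table = load_hydrolysis_table()
        nz = hydrolysis_partition(table, "NZ")["compounds"].set_index("compound")
        ch = hydrolysis_partition(table, "CH")["compounds"].set_index("compound")
        assert nz.loc["goitrin", "pct_display"] == 12.4
        assert nz.loc["epithio-2OH3B-I", "pct_display"] == 21.8
        assert nz.loc["allyl-ITC", "pct_display"] == 14.4
        assert ch.loc["goitrin", "pct_display"] == 60.7
        assert ch.loc["allyl-ITC", "pct_display"] == 38.7

    def test_class_sums_both_conventions(self):
        """Summary rows follow the sum-of-rounded convention: the NZ
        isothiocyanate fraction is 35.3 only as a sum of rounded compound
        percentages (35.40 at full precision). From the printed NZ means the
        nitrile rounded sum is 64.6 (one row of the source summary table,
        5.3 for 2OH3but-CN, is not recomputable from its own printed mean:
        590/11242 = 5.248 -> 5.2)."""
        table = load_hydrolysis_table()
        classes = hydrolysis_partition(table, "NZ")["classes"]
        assert classes.loc["isothiocyanate", "pct_rounded_sum"] == pytest.approx(35.3)
        assert classes.loc["isothiocyanate", "pct_full"] == pytest.approx(35.4, abs=0.05)
        assert classes.loc["nitrile/epithionitrile", "pct_rounded_sum"] == pytest.approx(64.6)
        assert classes["pct_full"].sum() == pytest.approx(100.0, abs=0.1)

    def test_single_product_species(self):
        table = pd.DataFrame(
            [{"species": "X", "parent_glucosinolate": "allyl", "compound": "allyl-ITC",
              "product_class": "isothiocyanate", "mean": 42.0, "sd": 1.0}]
        )
        part = hydrolysis_partition(table, "X")
        assert part["compounds"]["pct_display"].iloc[0] == 100.0

    def test_scale_invariance(self):
        table = load_hydrolysis_table()
        scaled = table.assign(mean=table["mean"] * 7.5)
        a = hydrolysis_partition(table, "CH")["compounds"]["pct"]
        b = hydrolysis_partition(scaled, "CH")["compounds"]["pct"]
        np.testing.assert_allclose(a, b)

    def test_unknown_species(self):
        with pytest.raises(DataError):
            hydrolysis_partition(load_hydrolysis_table(), "XX")


def _de_table(rows):
    return pd.DataFrame(rows, columns=["locus", "contrast", "log2fc", "stat", "p_raw", "p_adj"])


class TestChemotypeRules:
    def test_esp_protein_up_predicts_nitriles(self):
        de_p = _de_table([["At1g54040", "NZ_vs_CH+EX", 3.0, 5.0, 1e-4, 1e-3]])
        preds = predict_chemotype({"P": de_p}, load_chemotype_rules())
        assert len(preds) == 1
        assert preds.iloc[0]["prediction_type"] == "nitriles"
        assert preds.iloc[0]["species"] == "NZ"

    def test_empty_tables_no_predictions(self):
        preds = predict_chemotype({"P": _de_table([])}, load_chemotype_rules())
        assert preds.empty

    def test_conflicting_c4_claims_flagged(self):
        """Protein evidence for C4 up in NZ vs transcript evidence for C4 up
        in CH over NZ: both claims emitted, both flagged."""
        de_p = _de_table([["At2g43100", "NZ_vs_CH+EX", 2.0, 5.0, 1e-4, 1e-3]])
        de_t = _de_table([["At5g23010", "CH_vs_NZ", 1.5, 4.0, 1e-3, 1e-2]])
        preds = predict_chemotype({"P": de_p, "T": de_t}, load_chemotype_rules())
        assert len(preds) == 2
        assert preds["conflict"].all()

    def test_malformed_rules_rejected(self):
        rules = load_chemotype_rules().drop(columns=["prediction_type"])
        with pytest.raises(ConfigError):
            predict_chemotype({}, rules)
        bad = load_chemotype_rules().assign(direction="sideways")
        with pytest.raises(ConfigError):
            predict_chemotype({}, bad)


class TestEvaluatePredictions:
    def _profile(self, ch_c4=50.0, nz_c4=20.0, n=6, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        ann = load_compound_annotations()
        cols, data, species = [], [], {}
        for sp, c4 in [("CH", ch_c4), ("EX", 5.0), ("NZ", nz_c4)]:
            for r in range(n):
                vec = pd.Series(0.0, index=ann.index)
                vec["S-2OH3-butenyl"] = c4 * (1 + noise * rng.standard_normal())
                vec["allyl"] = 10.0 * (1 + noise * rng.standard_normal())
                col = f"{sp}_m{r}"
                cols.append(col)
                data.append(vec.clip(lower=0))
                species[col] = sp
        conc = pd.concat(data, axis=1)
        conc.columns = cols
        return MetaboliteProfile(conc, ann, pd.Series(species))

    def test_supported_nitrile_claim(self):
        preds = pd.DataFrame(
            [{"rule_id": "r", "locus": "At1g54040", "symbol": "ESP", "layer": "P",
              "contrast": "NZ_vs_CH+EX", "direction": "up", "prediction_type": "nitriles",
              "species": "NZ", "versus": "rest", "versus_expanded": ("CH", "EX"),
              "conflict": False}]
        )
        out = evaluate_predictions(preds, None, load_hydrolysis_table())
        assert out["predictions"].iloc[0]["verdict"] == "supported"  # NZ: 64.7% nitriles

    def test_tie_is_untestable_not_contradicted(self):
        profile = self._profile(ch_c4=30.0, nz_c4=30.0)
        preds = pd.DataFrame(
            [{"rule_id": "r", "locus": "x", "symbol": "MAM1", "layer": "T",
              "contrast": "CH_vs_NZ", "direction": "up", "prediction_type": "c4_higher",
              "species": "CH", "versus": "NZ", "versus_expanded": ("NZ",),
              "conflict": False}]
        )
        out = evaluate_predictions(preds, profile, None)
        assert out["predictions"].iloc[0]["verdict"] == "untestable"

    def test_layer_accuracies_protein_beats_transcript(self):
        """Fixture mirroring the study outcome: the protein-layer C4 and
        nitrile claims hold, the transcript-layer C4 claim points the wrong
        way, so protein accuracy exceeds transcript accuracy."""
        profile = self._profile(ch_c4=20.0, nz_c4=60.0, noise=0.05, seed=3)
        preds = pd.DataFrame(
            [
                {"rule_id": "p1", "locus": "At2g43100", "symbol": "MAM-I", "layer": "P",
                 "contrast": "NZ_vs_CH+EX", "direction": "up", "prediction_type": "c4_higher",
                 "species": "NZ", "versus": "CH,EX", "versus_expanded": ("CH", "EX"),
                 "conflict": False},
                {"rule_id": "p2", "locus": "At1g54040", "symbol": "ESP", "layer": "P",
                 "contrast": "NZ_vs_CH+EX", "direction": "up", "prediction_type": "nitriles",
                 "species": "NZ", "versus": "rest", "versus_expanded": ("CH", "EX"),
                 "conflict": False},
                {"rule_id": "t1", "locus": "At5g23010", "symbol": "MAM1", "layer": "T",
                 "contrast": "CH_vs_NZ", "direction": "up", "prediction_type": "c4_higher",
                 "species": "CH", "versus": "NZ", "versus_expanded": ("NZ",),
                 "conflict": False},
            ]
        )
        out = evaluate_predictions(preds, profile, load_hydrolysis_table())
        acc = out["accuracy"]
        assert acc["P"] == 1.0
        assert acc["T"] == 0.0
        verdicts = out["predictions"].set_index("rule_id")["verdict"]
        assert verdicts["t1"] == "contradicted"
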