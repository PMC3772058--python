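import numpy as np
import pandas as pd
import pytest

from _oracles import oracle_kendall_tau_b
from timma import sirna


def records(rows):
    return pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "replicate", "inhibition_pct", "edge"]
    )


class TestQcAndAverage:
    def test_concordant_replicates_averaged(self):
        df = records([("g1", "g2", 1, 40.0, False), ("g1", "g2", 2, 44.0, True)])
        out = sirna.qc_and_average(df)
        assert out.loc[0, "inhibition_pct"] == pytest.approx(42.0)
        assert out.loc[0, "n_replicates_used"] == 2

    def test_discordant_edge_replicate_dropped(self):
        df = records([("g1", "g2", 1, 30.0, False), ("g1", "g2", 2, 50.0, True)])
        out = sirna.qc_and_average(df)
        assert out.loc[0, "inhibition_pct"] == pytest.approx(30.0)
        assert out.loc[0, "n_replicates_used"] == 1

    def test_discordant_without_edge_kept_with_warning(self):
        df = records([("g1", "g2", 1, 30.0, False), ("g1", "g2", 2, 50.0, False)])
        with pytest.warns(UserWarning, match="discordant"):
            out = sirna.qc_and_average(df)
        assert out.loc[0, "inhibition_pct"] == pytest.approx(40.0)

    def test_boundary_discordance_is_kept(self):
        df = records([("g1", "g2", 1, 30.0, False), ("g1", "g2", 2, 45.0, True)])
        out = sirna.qc_and_average(df)  # difference exactly 15: not discordant
        assert out.loc[0, "inhibition_pct"] == pytest.approx(37.5)

    def test_output_within_replicate_range(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(30):
            v = rng.uniform(0, 100, size=2)
            rows += [
                (f"g{i}", f"h{i}", 1, v[0], bool(rng.integers(0, 2))),
                (f"g{i}", f"h{i}", 2, v[1], bool(rng.integers(0, 2))),
            ]
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = sirna.qc_and_average(records(rows))
        raw = records(rows)
        for _, r in out.iterrows():
            grp = raw[(raw["gene_a"] == r["gene_a"]) & (raw["gene_b"] == r["gene_b"])]
            assert grp["inhibition_pct"].min() - 1e-9 <= r["inhibition_pct"]
            assert r["inhibition_pct"] <= grp["inhibition_pct"].max() + 1e-9

    def test_edge_annotation_from_plate_positions(self):
        df = pd.DataFrame(
            {
                "gene_a": ["g1", "g2"],
                "gene_b": [None, None],
                "replicate": [1, 1],
                "inhibition_pct": [10.0, 20.0],
                "plate": [1, 1],
                "row": [1, 5],
                "col": [10, 10],
            }
        )
        out = sirna.annotate_edge_wells(df)
        assert out["edge"].tolist() == [True, False]


class TestNormalizeSingles:
    def test_no_weaker_doubles_leaves_single_unchanged(self):
        singles = pd.Series({"g": 50.0})
        doubles = pd.DataFrame(
            {"gene_a": ["g", "g"], "gene_b": ["h", "k"], "inhibition_pct": [60.0, 70.0]}
        )
        out = sirna.normalize_single_knockdown(singles, doubles)
        assert out["g"] == 50.0

    def test_weaker_doubles_pull_single_down(self):
        singles = pd.Series({"g": 50.0})
        doubles = pd.DataFrame(
            {
                "gene_a": ["g", "h", "g"],
                "gene_b": ["h", "g", "k"],
                "inhibition_pct": [40.0, 30.0, 60.0],
            }
        )
        out = sirna.normalize_single_knockdown(singles, doubles)
        assert out["g"] == pytest.approx(40.0)  # mean(50, 40, 30)

    def test_gene_absent_from_doubles_unchanged(self):
        singles = pd.Series({"g": 33.0})
        doubles = pd.DataFrame(
            {"gene_a": ["a"], "gene_b": ["b"], "inhibition_pct": [10.0]}
        )
        assert sirna.normalize_single_knockdown(singles, doubles)["g"] == 33.0

    def test_never_increases(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(10)]
        singles = pd.Series({g: rng.uniform(0, 100) for g in genes})
        rows = [
            {
                "gene_a": genes[i],
                "gene_b": genes[j],
                "inhibition_pct": rng.uniform(0, 100),
            }
            for i in range(10)
            for j in range(i + 1, 10)
        ]
        out = sirna.normalize_single_knockdown(singles, pd.DataFrame(rows))
        assert (out <= singles + 1e-9).all()


class TestSirnaSynergy:
    def test_zero_singles_pass_through(self):
        singles = pd.Series({"a": 0.0, "b": 0.0})
        doubles = pd.DataFrame(
            {"gene_a": ["a"], "gene_b": ["b"], "inhibition_pct": [63.399]}
        )
        out = sirna.sirna_synergy(singles, doubles)
        assert out.loc[0, "synergy_pct"] == pytest.approx(63.399)
        out_p = sirna.sirna_synergy(singles, doubles, null="product")
        assert out_p.loc[0, "synergy_pct"] == pytest.approx(63.399)

    def test_null_expectation_scores_zero(self):
        # 20% and 30% singles give a 44% independence expectation
        singles = pd.Series({"a": 20.0, "b": 30.0})
        doubles = pd.DataFrame(
            {"gene_a": ["a"], "gene_b": ["b"], "inhibition_pct": [44.0]}
        )
        out = sirna.sirna_synergy(singles, doubles)
        assert out.loc[0, "synergy_pct"] == pytest.approx(0.0)

    def test_missing_single_gives_na(self):
        singles = pd.Series({"a": 20.0})
        doubles = pd.DataFrame(
            {"gene_a": ["a"], "gene_b": ["zz"], "inhibition_pct": [50.0]}
        )
        assert np.isnan(sirna.sirna_synergy(singles, doubles).loc[0, "synergy_pct"])


class TestCompare:
    def _tables(self, predicted_synergy, measured_synergy, efficacy=None):
        pairs = [(f"n{i}", f"m{i}") for i in range(len(predicted_synergy))]
        pred = pd.DataFrame(
            {
                "node_a": [a for a, _ in pairs],
                "node_b": [b for _, b in pairs],
                "predicted_synergy": predicted_synergy,
            }
        )
        if efficacy is not None:
            pred["predicted_efficacy"] = efficacy
        meas = pd.DataFrame(
            {
                "gene_a": [a for a, _ in pairs],
                "gene_b": [b for _, b in pairs],
                "synergy_pct": measured_synergy,
            }
        )
        return pred, meas

    def test_identical_ranks_tau_one(self):
        pred, meas = self._tables([0.1, 0.2, 0.3, 0.4], [10, 20, 30, 40])
        rep = sirna.compare_predicted_measured(pred, meas)
        assert rep["kendall_tau"] == pytest.approx(1.0)

    def test_reversed_ranks_tau_minus_one(self):
        pred, meas = self._tables([0.1, 0.2, 0.3, 0.4], [40, 30, 20, 10])
        rep = sirna.compare_predicted_measured(pred, meas)
        assert rep["kendall_tau"] == pytest.approx(-1.0)

    def test_tau_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.choice([0.1, 0.2, 0.3, 0.5], size=12)
        m = rng.uniform(0, 50, size=12)
        pred, meas = self._tables(x, m)
        rep = sirna.compare_predicted_measured(pred, meas)
        assert rep["kendall_tau"] == pytest.approx(oracle_kendall_tau_b(x, m))

    def test_too_few_pairs_gives_na(self):
        pred, meas = self._tables([0.1, 0.2], [10, 20])
        rep = sirna.compare_predicted_measured(pred, meas)
        assert np.isnan(rep["kendall_tau"])

    def test_high_low_grouping_reported(self):
        pred, meas = self._tables(
            [0.1, 0.2, 0.3, 0.4, 0.5, 0.6],
            [5, 10, 12, 30, 40, 50],
            efficacy=[0.2, 0.3, 0.4, 0.8, 0.9, 0.95],
        )
        rep = sirna.compare_predicted_measured(pred, meas)
        assert rep["n_high"] == 3 and rep["n_low"] == 3
        assert rep["high_mean_measured"] > rep["low_mean_measured"]
        assert 0 <= rep["high_vs_low_p_bonferroni"] <= 1

    def test_gene_to_node_mapping_averages_within_node_pairs(self):
        pred = pd.DataFrame(
            {
                "node_a": ["N1"],
                "node_b": ["N2"],
                "predicted_synergy": [0.5],
            }
        )
        meas = pd.DataFrame(
            {
                "gene_a": ["k1", "k2"],
                "gene_b": ["k3", "k4"],
                "synergy_pct": [20.0, 40.0],
            }
        )
        mapping = pd.DataFrame(
            {
                "gene_a": ["k1", "k2"],
                "gene_b": ["k3", "k4"],
                "node_a": ["N1", "N1"],
                "node_b": ["N2", "N2"],
            }
        )
        rep = sirna.compare_predicted_measured(pred, meas, mapping)
        assert rep["n_pairs"] == 1  # averaged to one node pair (30%)
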