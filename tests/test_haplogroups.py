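import numpy as np
import pandas as pd
import pytest

import ystrpop as ys
from ystrpop import datasets
from ystrpop.simulate import simulate_haplogroup_panel

from conftest import make_table


def modal_panel(modals, epsilon=1e-4, priors=None):
    """Panel whose per-haplogroup tables put all mass on the modal alleles."""
    freqs = {
        hg: {locus: {float(a): 1.0} for locus, a in zip(modals.columns, row)}
        for hg, row in modals.iterrows()
    }
    if priors is None:
        priors = {hg: 1.0 for hg in freqs}
    return ys.HaplogroupReferencePanel(freqs, priors, epsilon)


@pytest.fixture
def two_group_modals():
    return pd.DataFrame(
        [[14, 30, 11], [17, 27, 14]], index=["H1", "H2"], columns=["L1", "L2", "L3"]
    )


class TestTrainPanel:
    def test_modal_training_gives_unit_frequencies(self, two_group_modals):
        rows = np.repeat(two_group_modals.to_numpy(), 10, axis=0)
        t = make_table(rows, ["X"] * 20, loci=list(two_group_modals.columns))
        labels = pd.Series(["H1"] * 10 + ["H2"] * 10, index=t.alleles.index)
        panel = ys.train_panel(t, labels)
        for hg in ("H1", "H2"):
            for locus in t.loci:
                assert max(panel.frequencies[hg][locus].values()) == 1.0

    def test_frequencies_normalized(self):
        rng = np.random.default_rng(0)
        t = make_table(rng.integers(10, 16, (30, 4)).astype(float), ["X"] * 30)
        labels = pd.Series(rng.choice(["A", "B", "C"], 30), index=t.alleles.index)
        panel = ys.train_panel(t, labels)
        for hg, table in panel.frequencies.items():
            for locus, freqs in table.items():
                assert sum(freqs.values()) == pytest.approx(1.0, abs=1e-12)

    def test_self_prediction_perfect_on_disjoint_modals(self, two_group_modals):
        rows = np.repeat(two_group_modals.to_numpy(), 5, axis=0)
        t = make_table(rows, ["X"] * 10, loci=list(two_group_modals.columns))
        labels = pd.Series(["H1"] * 5 + ["H2"] * 5, index=t.alleles.index)
        panel = ys.train_panel(t, labels)
        preds = ys.predict_table(t, panel)
        assert (preds["haplogroup"].to_numpy() == labels.to_numpy()).all()


class TestPredict:
    def test_modal_match_dominates(self, two_group_modals):
        panel = modal_panel(two_group_modals)
        pred = ys.predict_haplogroup({"L1": 14, "L2": 30, "L3": 11}, panel)
        assert pred.haplogroup == "H1"
        assert pred.posteriors["H1"] > 0.999
        assert pred.fitness == pytest.approx(0.0)  # log10(1) per locus

    def test_identical_tables_give_uniform_posterior(self):
        modals = pd.DataFrame([[14, 30]] * 3, index=["A", "B", "C"], columns=["L1", "L2"])
        pred = ys.predict_haplogroup({"L1": 14, "L2": 30}, modal_panel(modals))
        for p in pred.posteriors.values():
            assert p == pytest.approx(1 / 3)
        assert pred.haplogroup == "A"  # alphabetical tie-break

    def test_prior_scale_invariance(self, two_group_modals):
        panel = modal_panel(two_group_modals)
        q = {"L1": 14, "L2": 27, "L3": 11}
        p1 = ys.predict_haplogroup(q, panel, priors={"H1": 0.3, "H2": 0.7})
        p2 = ys.predict_haplogroup(q, panel, priors={"H1": 30, "H2": 70})
        assert p1.posteriors == pytest.approx(p2.posteriors)

    def test_unscorable_locus_does_not_change_posterior(self, two_group_modals):
        panel = modal_panel(two_group_modals)
        q = {"L1": 14, "L2": 30, "L3": 14}
        with_extra = dict(q, DYS999=12)
        assert (
            ys.predict_haplogroup(q, panel).posteriors
            == ys.predict_haplogroup(with_extra, panel).posteriors
        )

    def test_multicopy_pair_order_insensitive(self):
        modals = pd.DataFrame(
            [[11, 14], [13, 17]], index=["A", "B"], columns=["DYS385a", "DYS385b"]
        )
        panel = modal_panel(modals)
        p1 = ys.predict_haplogroup({"DYS385a": 11, "DYS385b": 14}, panel)
        p2 = ys.predict_haplogroup({"DYS385a": 14, "DYS385b": 11}, panel)
        assert p1.posteriors == p2.posteriors

    def test_no_shared_loci_rejected(self, two_group_modals):
        with pytest.raises(ValueError, match="no loci"):
            ys.predict_haplogroup({"DYS999": 12}, modal_panel(two_group_modals))

    def test_panel_csv_round_trip(self, two_group_modals, tmp_path):
        panel = modal_panel(two_group_modals)
        panel.to_csv(tmp_path / "panel.csv")
        back = ys.HaplogroupReferencePanel.read_csv(tmp_path / "panel.csv")
        assert back.frequencies == panel.frequencies

    def test_accuracy_monotone_in_noise(self):
        sizes = {f"H{i}": 20 for i in range(10)}
        accs = []
        for noise in (0.05, 0.35, 0.65):
            sim = simulate_haplogroup_panel(
                sizes, [f"L{i}" for i in range(8)], noise=noise, seed=99,
                min_step_distance=6,
            )
            preds = ys.predict_table(sim.test_table, sim.panel)
            accs.append((preds["haplogroup"].to_numpy() == sim.test_labels.to_numpy()).mean())
        assert accs[0] >= accs[1] >= accs[2]


class TestFrequencyTable:
    def test_published_regional_composition(self):
        counts = datasets.croatia_haplogroup_counts()
        hgs = pd.Series(
            [hg for region in counts.index for hg, c in counts.loc[region].items() for _ in range(c)]
        )
        regions = pd.Series(
            [region for region in counts.index for c in counts.loc[region] for _ in range(c)]
        )
        table = ys.haplogroup_frequency_table(hgs, regions)
        pct = table.percentages
        assert round(pct.loc["Total", "I2a"], 1) == 39.0
        assert round(pct.loc["Total", "R1a"], 2) == 24.32
        assert round(pct.loc["Total", "E1b1b"], 2) == 10.81
        assert round(pct.loc["Hvar", "I2a"], 2) == 52.88
        assert round(pct.loc["Hvar", "R1a"], 2) == 10.58
        assert table.counts.loc["Total"].sum() == 518

    def test_rows_sum_to_group_sizes_and_100(self):
        rng = np.random.default_rng(1)
        hgs = pd.Series(rng.choice(["A", "B", "C"], 50))
        grp = pd.Series(rng.choice(["g1", "g2"], 50))
        t = ys.haplogroup_frequency_table(hgs, grp)
        assert (t.counts.drop("Total").sum(axis=1).to_numpy() == grp.value_counts().loc[t.counts.index[:-1]].to_numpy()).all()
        np.testing.assert_allclose(t.percentages.sum(axis=1), 100.0, atol=0.01)

    def test_single_group_single_haplogroup(self):
        t = ys.haplogroup_frequency_table(pd.Series(["A", "A"]), pd.Series(["g", "g"]))
        assert t.percentages.loc["g", "A"] == 100.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ys.haplogroup_frequency_table(pd.Series([], dtype=str), pd.Series([], dtype=str))
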