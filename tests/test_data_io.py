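import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

import ystrpop as ys
from ystrpop.data_io import MultiCopyLocusPolicy
from ystrpop.simulate import SimulationConfig, simulate_split_populations

from conftest import make_table


class TestReadWrite:
    def test_round_trip_identity(self, toy_table, tmp_path):
        path = tmp_path / "t.csv"
        ys.write_haplotype_table(toy_table, path)
        back = ys.read_haplotype_table(path, known_loci=None)
        assert back.equals(toy_table)

    def test_microvariant_parsed_as_exact_decimal(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("SampleID,Population,DYS458\na,X,13.2\nb,X,17\n")
        t = ys.read_haplotype_table(path)
        assert t.alleles.loc["a", "DYS458"] == 13.2

    def test_malformed_cell_names_sample_and_locus(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("SampleID,Population,DYS19,DYS392\na,X,14,11\nb,X,abc,12\n")
        with pytest.raises(ValueError, match=r"'abc'.*'b'.*'DYS19'"):
            ys.read_haplotype_table(path)

    def test_duplicate_sample_id_rejected(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("SampleID,Population,DYS19\na,X,14\na,X,15\n")
        with pytest.raises(ValueError, match="duplicate"):
            ys.read_haplotype_table(path)

    def test_unknown_locus_warned_but_retained(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("SampleID,Population,DYS19,MYSTERY1\na,X,14,10\nb,X,15,11\n")
        with pytest.warns(UserWarning, match="MYSTERY1"):
            t = ys.read_haplotype_table(path)
        assert "MYSTERY1" in t.loci

    def test_tsv_dialect(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("SampleID\tPopulation\tDYS19\na\tX\t14\nb\tX\tNA\n")
        t = ys.read_haplotype_table(path)
        assert np.isnan(t.alleles.loc["b", "DYS19"])

    def test_invalid_fractional_part_rejected(self):
        with pytest.raises(ValueError, match="invalid allele"):
            make_table([[14.5], [15.0]], ["A", "A"])


class TestMultiCopyPolicy:
    def test_sorted_ascending_and_idempotent(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "SampleID,Population,DYS385a,DYS385b\na,X,17,11\nb,X,11,14\n"
        )
        t = ys.read_haplotype_table(path)
        assert t.alleles.loc["a", "DYS385a"] == 11 and t.alleles.loc["a", "DYS385b"] == 17
        again = MultiCopyLocusPolicy().normalize(t.alleles)
        pd.testing.assert_frame_equal(again, t.alleles)

    def test_as_reported_leaves_order(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("SampleID,Population,DYS385a,DYS385b\na,X,17,11\n")
        t = ys.read_haplotype_table(path, policy=MultiCopyLocusPolicy(rule="as_reported"))
        assert t.alleles.loc["a", "DYS385a"] == 17

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError, match="rule"):
            MultiCopyLocusPolicy(rule="random")


class TestRegistryFilter:
    def test_partition_preserves_samples_and_order(self, toy_table):
        registry = ys.AlleleRegistry.from_table(toy_table)
        retained, flagged = ys.filter_by_registry(toy_table, registry)
        assert retained.sample_ids == toy_table.sample_ids and flagged.n_samples == 0

    def test_flags_sample_with_unregistered_microvariant(self):
        t = make_table(
            [[14, 11], [14, 12], [15, 11], [16, 11], [14.2, 12]],
            ["A"] * 5,
        )
        integer_only = ys.AlleleRegistry(
            {"L1": frozenset({14.0, 15.0, 16.0}), "L2": frozenset({11.0, 12.0})}
        )
        retained, flagged = ys.filter_by_registry(t, integer_only)
        assert retained.n_samples == 4
        assert flagged.sample_ids == ["s5"]

    def test_empty_registry_rejected_when_not_covering(self, toy_table):
        with pytest.raises(ValueError, match="cover"):
            ys.filter_by_registry(toy_table, ys.AlleleRegistry({}))

    def test_registry_csv_round_trip(self, toy_table, tmp_path):
        reg = ys.AlleleRegistry.from_table(toy_table)
        reg.to_csv(tmp_path / "reg.csv")
        back = ys.AlleleRegistry.read_csv(tmp_path / "reg.csv")
        assert back.alleles == reg.alleles

    def test_synthetic_planting_mirrors_published_split(self):
        cfg = SimulationConfig(
            n_populations=5, samples_per_population=104, loci=tuple(f"L{i}" for i in range(10)),
            seed=42,
        )
        base = simulate_split_populations(cfg)
        base = base.select_samples(base.sample_ids[:518])
        registry = ys.AlleleRegistry.from_table(base)
        planted = ys.plant_microvariants(base, 11, seed=7)
        retained, flagged = ys.filter_by_registry(planted, registry)
        assert (retained.n_samples, flagged.n_samples) == (507, 11)


class TestNewick:
    def test_three_leaf_star(self, tmp_path):
        tree = ys.neighbor_joining(
            np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0]], dtype=float), labels=["A", "B", "C"]
        )
        ys.write_newick(tree, tmp_path / "t.nwk")
        text = (tmp_path / "t.nwk").read_text()
        assert sorted(x.split(":")[0] for x in text.strip("();\n").split(",")) == ["A", "B", "C"]

    def test_round_trip_topology_and_lengths(self, tmp_path):
        rng = np.random.default_rng(0)
        pts = rng.random((6, 2))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        tree = ys.neighbor_joining(D)
        ys.write_newick(tree, tmp_path / "t.nwk")
        back = ys.read_newick(tmp_path / "t.nwk")
        d1 = tree.tip_tip_distances()
        d2 = back.tip_tip_distances(endpoints=list(d1.ids))
        np.testing.assert_allclose(d1.data, d2.data, atol=1e-9)

    def test_label_with_space_is_quoted(self, tmp_path):
        tree = TreeNode.read(["('North Island':1,B:1,C:1);"])
        ys.write_newick(tree, tmp_path / "t.nwk")
        back = ys.read_newick(tmp_path / "t.nwk")
        assert {t.name for t in back.tips()} == {"North Island", "B", "C"}

    def test_unlabeled_leaf_rejected(self, tmp_path):
        tree = TreeNode(children=[TreeNode(name="A"), TreeNode()])
        with pytest.raises(ValueError, match="unlabeled"):
            ys.write_newick(tree, tmp_path / "t.nwk")


class TestReportBundle:
    @staticmethod
    def _results(seed):
        cfg = SimulationConfig(n_populations=2, samples_per_population=12, seed=seed)
        table = simulate_split_populations(cfg)
        dm = ys.rst_matrix(table, m=99, seed=seed)
        return {
            "allele_frequencies": [ys.allele_frequencies(table, l) for l in table.loci],
            "diversity": ys.haplotype_statistics(table),
            "rst": dm,
            "mds": ys.classical_mds(dm),
            "manifest": {"seed": seed},
        }

    def test_bundle_files_written(self, tmp_path):
        written = ys.write_report_bundle(self._results(1), tmp_path / "out")
        for f in written:
            assert f.exists(), f

    def test_rerun_same_seed_byte_identical(self, tmp_path):
        ys.write_report_bundle(self._results(5), tmp_path / "a")
        ys.write_report_bundle(self._results(5), tmp_path / "b")
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes(), f.name

    def test_empty_results_rejected_before_writing(self, tmp_path):
        with pytest.raises(ValueError):
            ys.write_report_bundle({}, tmp_path / "out")
        assert not (tmp_path / "out").exists()
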