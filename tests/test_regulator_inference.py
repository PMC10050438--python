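"""Correlation, homolog collapsing and the two-tier nomination cascade."""

import math

import numpy as np
import pandas as pd
import pytest

from regnominate.motif_scan import MotifModel, TFBSCountMatrix
from regnominate.regulator_inference import (
    AbundanceTable,
    CorrelationReport,
    RegulatorReport,
    correlate_tf_abundance,
    infer_tier2,
    nominate_tier1,
    pearson_r,
)

from conftest import brute_pearson, make_promoter


def matrix_of(counts, gene_ids=None):
    counts = np.atleast_2d(np.asarray(counts))
    gene_ids = gene_ids or [f"g{j}" for j in range(counts.shape[1])]
    return TFBSCountMatrix(
        tf_names=[f"tf{i}" for i in range(counts.shape[0])],
        gene_ids=gene_ids,
        counts=counts,
    )


class TestCorrelate:
    def test_identity_gives_r_one(self):
        ab = AbundanceTable(["g0", "g1", "g2"], [1.0, 2.0, 5.0])
        (rep,) = correlate_tf_abundance(matrix_of([[1, 2, 5]]), ab)
        assert rep.r == pytest.approx(1.0)
        assert rep.positive

    def test_exact_anticorrelation(self):
        ab = AbundanceTable(["g0", "g1", "g2", "g3"], [4.0, 3.0, 2.0, 1.0])
        (rep,) = correlate_tf_abundance(matrix_of([[1, 2, 3, 4]]), ab)
        assert rep.r == pytest.approx(-1.0)
        assert not rep.positive

    def test_hand_computed_sigma_formula_value(self):
        # counts (0,1,2) vs abundance (1,2,4): r = 9 / sqrt(84)
        ab = AbundanceTable(["g0", "g1", "g2"], [1.0, 2.0, 4.0])
        (rep,) = correlate_tf_abundance(matrix_of([[0, 1, 2]]), ab)
        assert rep.r == pytest.approx(9 / math.sqrt(84), abs=1e-12)

    def test_zero_variance_vector_undefined(self):
        ab = AbundanceTable(["g0", "g1", "g2"], [1.0, 2.0, 4.0])
        (rep,) = correlate_tf_abundance(matrix_of([[3, 3, 3]]), ab)
        assert rep.r is None
        assert not rep.positive

    def test_fewer_than_three_genes_rejected(self):
        with pytest.raises(ValueError):
            AbundanceTable(["g0", "g1"], [1.0, 2.0])

    def test_missing_gene_in_matrix_rejected(self):
        ab = AbundanceTable(["g0", "g1", "gX"], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="gX"):
            correlate_tf_abundance(matrix_of([[1, 2, 3]]), ab)

    def test_agrees_with_sum_formula_oracle(self):
        """1e-12 agreement with the plain-Python sum formula on random
        vector pairs."""
        rng = np.random.default_rng(19)
        for _ in range(100):
            n = int(rng.integers(3, 40))
            x = rng.integers(0, 20, size=n).astype(float)
            y = rng.uniform(0, 100, size=n)
            if x.std() == 0:
                x[0] += 1
            assert pearson_r(x, y) == pytest.approx(brute_pearson(x, y), abs=1e-12)

    def test_gene_permutation_invariance(self):
        rng = np.random.default_rng(23)
        counts = rng.integers(0, 10, size=(5, 13))
        ab_vals = rng.uniform(1, 100, size=13)
        gene_ids = [f"g{j}" for j in range(13)]
        base = correlate_tf_abundance(
            matrix_of(counts, gene_ids), AbundanceTable(gene_ids, ab_vals)
        )
        perm = rng.permutation(13)
        shuffled = correlate_tf_abundance(
            matrix_of(counts[:, perm], [gene_ids[j] for j in perm]),
            AbundanceTable(gene_ids, ab_vals),
        )
        for a, b in zip(base, shuffled):
            assert a.r == pytest.approx(b.r, abs=1e-12)


def expr_frame(rows):
    return pd.DataFrame(rows, columns=["gene_id", "g_fpkm", "c_fpkm", "fc", "expr_class"])


class TestNominateTier1:
    def test_shared_host_collapses_to_single_entry(self):
        reports = [CorrelationReport("Gcn4", 0.44, 13, True),
                   CorrelationReport("Cpc1", 0.40, 13, True)]
        expr = expr_frame([("hostG", 5.0, 25.0, 5.0, "up")])
        report = nominate_tier1(reports, {"Gcn4": "hostG", "Cpc1": "hostG"}, expr)
        (entry,) = report.entries
        assert entry.member_tf_names == ("Cpc1", "Gcn4")
        assert entry.r == pytest.approx(0.44)  # max member r
        assert entry.expr_class == "up"

    def test_empty_positive_set_gives_empty_report(self):
        reports = [CorrelationReport("a", -0.5, 13, False),
                   CorrelationReport("b", None, 13, False)]
        report = nominate_tier1(reports, {"a": "h1", "b": "h2"}, expr_frame([]))
        assert report.entries == []

    def test_filter_and_merge_cascade_22_to_13(self):
        """22 positively correlated TFs, 7 without a host mapping, and
        two 2-way homolog merges leave 13 regulators, ranked by r with
        the three strongest correlations on top."""
        rng = np.random.default_rng(29)
        named = {"Rox1": 0.64, "Ste12": 0.54, "Gcn4": 0.44, "Cpc1": 0.40,
                 "Mig1": 0.30, "Cre1": 0.28}
        others = {f"pos{i}": float(r)
                  for i, r in enumerate(rng.uniform(0.01, 0.25, size=16))}
        positive = {**named, **others}
        assert len(positive) == 22
        reports = [CorrelationReport(tf, r, 13, True) for tf, r in positive.items()]
        reports += [CorrelationReport(f"neg{i}", -0.3, 13, False) for i in range(29)]

        homolog_map = {"Rox1": "hR", "Ste12": "hS",
                       "Gcn4": "hG", "Cpc1": "hG",     # merge
                       "Mig1": "hM", "Cre1": "hM"}     # merge
        for i in range(9):  # 9 more mapped singletons -> 15 mapped TFs
            homolog_map[f"pos{i}"] = f"h{i}"
        # pos9..pos15 (7 TFs) have no mapping and are dropped

        expr = expr_frame([(h, 10.0, 30.0, 3.0, "up")
                           for h in set(homolog_map.values())])
        report = nominate_tier1(reports, homolog_map, expr)
        assert len(report.entries) == 13
        assert sorted(report.unmapped_tfs) == sorted(f"pos{i}" for i in range(9, 16))
        assert [e.r for e in report.entries[:3]] == pytest.approx([0.64, 0.54, 0.44])
        assert report.entries[0].member_tf_names == ("Rox1",)
        merged = {e.host_gene_id: e.member_tf_names for e in report.entries}
        assert merged["hG"] == ("Cpc1", "Gcn4")
        assert merged["hM"] == ("Cre1", "Mig1")

    def test_collapse_partitions_mapped_tfs(self):
        """Every mapped positive TF lands in exactly one entry and the
        entry count never exceeds the TF count."""
        rng = np.random.default_rng(31)
        tfs = [f"tf{i}" for i in range(20)]
        reports = [CorrelationReport(tf, float(rng.uniform(0.1, 0.9)), 13, True)
                   for tf in tfs]
        homolog_map = {tf: f"h{rng.integers(0, 8)}" for tf in tfs}
        expr = expr_frame([(f"h{i}", 10.0, 30.0, 3.0, "up") for i in range(8)])
        report = nominate_tier1(reports, homolog_map, expr)
        members = [tf for e in report.entries for tf in e.member_tf_names]
        assert sorted(members) == sorted(tfs)
        assert len(report.entries) <= len(tfs)


class TestInferTier2:
    def test_cascade_fixture_partition_counts(self, cascade_fixture):
        """The full tier-2 cascade: 45 candidates, 10 unmapped, homolog
        merges to 30 regulators, 1 without expression data, 1 unchanged,
        12 up + 16 down."""
        fx = cascade_fixture
        report = infer_tier2(fx["tier1"], fx["promoters"], fx["motifs"],
                             fx["homolog_map"], fx["expr"])
        exp = fx["expected"]
        n_member_tfs = sum(len(e.member_tf_names) for e in report.entries)
        assert n_member_tfs + len(report.unmapped_tfs) == exp["n_candidates"]
        assert len(report.unmapped_tfs) == exp["n_unmapped"]
        assert len(report.entries) == exp["n_entries"]
        assert report.class_counts() == exp["class_counts"]

    def test_zero_hits_gives_empty_tier2(self, cascade_fixture):
        fx = cascade_fixture
        promoters = [make_promoter("A" * 400, gene_id=e.host_gene_id)
                     for e in fx["tier1"].entries]
        motifs = [MotifModel(tf_name="t", kind="consensus", consensus="CGCGCGCG")]
        report = infer_tier2(fx["tier1"], promoters, motifs,
                             fx["homolog_map"], fx["expr"])
        assert report.entries == [] and report.unmapped_tfs == []

    def test_empty_tier1_rejected(self, cascade_fixture):
        fx = cascade_fixture
        empty = RegulatorReport(tier=1, entries=[])
        with pytest.raises(ValueError):
            infer_tier2(empty, fx["promoters"], fx["motifs"],
                        fx["homolog_map"], fx["expr"])

    def test_single_tf_unique_induced_composition(self, cascade_fixture):
        """One TF hitting a tier-1 promoter whose host gene is expressed
        only under induction comes back as a unique_induced entry."""
        fx = cascade_fixture
        motif = MotifModel(tf_name="solo", kind="consensus", consensus="TTGACGTC")
        promoters = [make_promoter("A" * 50 + "TTGACGTC" + "A" * 50,
                                   gene_id=fx["tier1"].entries[0].host_gene_id)]
        expr = expr_frame([("hostX", 0.0, 40.0, None, "unique_induced")])
        report = infer_tier2(fx["tier1"], promoters, [motif], {"solo": "hostX"}, expr)
        (entry,) = report.entries
        assert entry.expr_class == "unique_induced"
        assert entry.member_tf_names == ("solo",)
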