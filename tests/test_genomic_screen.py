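import numpy as np
import pandas as pd
import pytest

from metasig.errors import DegenerateInputError, ParameterError
from metasig.genomic_screen import (
    cnv_survival_screen,
    cooccurrence_network,
    gene_mutation_matrix,
    group_burden_compare,
    ici_response_assoc,
    pair_table,
    prognostic_gene_screen,
    recurrent_genes,
)
from metasig.io_cohort import CnvRecord, IciRecord
from metasig.synthetic_cohort import SimConfig, simulate_survival


def _matrix(rows, genes, samples=None):
    samples = samples or [f"S{i}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=pd.Index(samples, name="sample_id"), columns=genes, dtype=bool)


class TestGeneMatrix:
    def test_construction_and_idempotence(self, make_snv):
        recs = [make_snv(sample="A", gene="TP53"), make_snv(sample="A", gene="TP53", pos=5), make_snv(sample="B", gene="KRAS")]
        M1 = gene_mutation_matrix(recs, ["A", "B"])
        M2 = gene_mutation_matrix(recs[::-1], ["A", "B"])
        assert M1.loc["A", "TP53"] and not M1.loc["B", "TP53"]
        assert (M1 == M2).all().all()


class TestRecurrentGenes:
    def test_boundary_five_percent(self):
        rows = [[i < 5, i < 4] for i in range(100)]
        M = _matrix(rows, ["keep", "drop"])
        assert recurrent_genes(M, 0.05) == ["keep"]

    def test_ceil_at_n421(self):
        rows = [[i < 22, i < 21] for i in range(421)]
        M = _matrix(rows, ["in22", "in21"])
        assert recurrent_genes(M, 0.05) == ["in22"]

    def test_sorted_by_frequency_then_name(self):
        rows = [[True, i < 8, i < 8] for i in range(10)]
        M = _matrix(rows, ["c", "b", "a"])
        assert recurrent_genes(M, 0.05) == ["c", "a", "b"]


class TestPrognosticScreen:
    def _cohort(self, seed, n=400, hr=0.5):
        rng = np.random.default_rng(seed)
        mut = rng.random(n) < 0.3
        null1 = rng.random(n) < 0.25
        null2 = rng.random(n) < 0.4
        M = _matrix(np.column_stack([mut, null1, null2]), ["HIT", "N1", "N2"])
        cfg = SimConfig(seed=seed)
        cov = pd.DataFrame({"m": mut.astype(float)}, index=M.index)
        surv = simulate_survival(cfg, cov, {"m": np.log(hr)}, rng=rng)
        clin = surv.copy()
        return M, clin

    def test_planted_protective_gene_flagged(self):
        M, clin = self._cohort(seed=1)
        out = prognostic_gene_screen(M, clin)
        row = out.set_index("gene").loc["HIT"]
        assert row["significant"]
        assert row["hr"] < 1
        assert abs(np.log(row["hr"]) - np.log(0.5)) < 2 * (np.log(row["ci_high"]) - np.log(row["hr"])) / 1.959964

    def test_zero_mutant_gene_skipped_with_warning(self):
        M, clin = self._cohort(seed=2)
        M["EMPTY"] = False
        with pytest.warns(UserWarning, match="EMPTY"):
            out = prognostic_gene_screen(M, clin)
        assert "EMPTY" not in set(out["gene"])

    def test_q_column_present(self):
        M, clin = self._cohort(seed=3)
        out = prognostic_gene_screen(M, clin)
        assert {"q", "significant"} <= set(out.columns)
        assert (out["q"] >= out["p"] - 1e-12).all()


class TestCooccurrence:
    def test_perfect_pair_small_n(self):
        col_a = [True] * 3 + [False] * 3
        M = _matrix(np.column_stack([col_a, col_a]), ["A", "B"])
        assocs, _ = cooccurrence_network(M)
        assert len(assocs) == 1
        a = assocs[0]
        assert a.p == pytest.approx(0.1, abs=1e-12)
        assert a.direction == "co-occurrence"
        assert (a.n_both, a.n_a_only, a.n_b_only, a.n_neither) == (3, 0, 0, 3)

    def test_mutual_exclusivity_direction(self):
        col_a = [True] * 3 + [False] * 3
        col_b = [not v for v in col_a]
        M = _matrix(np.column_stack([col_a, col_b]), ["A", "B"])
        assocs, _ = cooccurrence_network(M)
        assert assocs[0].direction == "mutual-exclusivity"

    def test_counts_sum_to_n(self):
        rng = np.random.default_rng(0)
        M = _matrix(rng.random((40, 4)) < 0.3, list("ABCD"))
        assocs, _ = cooccurrence_network(M)
        for a in assocs:
            assert a.n_both + a.n_a_only + a.n_b_only + a.n_neither == 40

    def test_single_gene_empty_network(self):
        M = _matrix([[True], [False]], ["A"])
        assocs, degree = cooccurrence_network(M)
        assert assocs == [] and degree.sum() == 0

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(5)
        M = _matrix(rng.random((30, 3)) < 0.4, list("ABC"))
        perm = rng.permutation(30)
        Mp = M.iloc[perm]
        p1 = pair_table(cooccurrence_network(M)[0])["p"]
        p2 = pair_table(cooccurrence_network(Mp)[0])["p"]
        assert np.allclose(p1, p2)

    def test_degree_counts_significant_edges(self):
        col = [True] * 10 + [False] * 10
        rng = np.random.default_rng(1)
        M = _matrix(np.column_stack([col, col, rng.random(20) < 0.5]), ["A", "B", "C"])
        _, degree = cooccurrence_network(M, fdr=0.1)
        assert degree["A"] >= 1 and degree["B"] >= 1


class TestCnvScreen:
    def _records(self, deleted_mask, gene, samples):
        return [
            CnvRecord(sample_id=s, gene=gene, call="deletion" if d else "neutral")
            for s, d in zip(samples, deleted_mask)
        ]

    def test_planted_deleterious_deletion_sign(self):
        rng = np.random.default_rng(7)
        n = 400
        samples = [f"S{i}" for i in range(n)]
        deleted = rng.random(n) < 0.15
        cfg = SimConfig(seed=7)
        cov = pd.DataFrame({"d": deleted.astype(float)}, index=pd.Index(samples, name="sample_id"))
        clin = simulate_survival(cfg, cov, {"d": np.log(1.7)}, rng=rng)
        records = self._records(deleted, "PTEN", samples)
        out = cnv_survival_screen(records, clin, adjust=())
        assert out.set_index("gene").loc["PTEN", "hr"] > 1

    def test_never_deleted_gene_skipped(self):
        samples = [f"S{i}" for i in range(20)]
        clin = pd.DataFrame(
            {"os_months": np.arange(1, 21, dtype=float), "os_event": [1] * 20},
            index=pd.Index(samples, name="sample_id"),
        )
        records = self._records([False] * 20, "NEVER", samples)
        with pytest.warns(UserWarning):
            out = cnv_survival_screen(records, clin, adjust=())
        assert len(out) == 0


class TestHotspots:
    def test_counts_sorted(self):
        from metasig.io_cohort import MutationRecord

        def rec(pc, pos):
            return MutationRecord(
                sample_id="S", gene="PTPRT", chrom="20", pos=pos, ref="C", alt="T",
                variant_classification="Missense_Mutation", variant_type="SNP",
                protein_change=pc,
            )

        from metasig.genomic_screen import hotspot_counts

        recs = [rec("R364Q", 1), rec("R364Q", 2), rec("E548K", 3)]
        counts = hotspot_counts(recs, "PTPRT")
        assert counts.index[0] == "R364Q" and counts.iloc[0] == 2

    def test_empty_for_unannotated(self):
        from metasig.genomic_screen import hotspot_counts

        assert hotspot_counts([], "TP53").empty


class TestGroupBurden:
    def test_two_group_dispatch(self):
        res = group_burden_compare([1, 2, 3, 4, 5, 6], ["a", "a", "a", "b", "b", "b"])
        assert res.method.startswith("wilcoxon")

    def test_three_group_dispatch(self):
        res = group_burden_compare([1, 2, 3, 4, 5, 6], ["a", "a", "b", "b", "c", "c"])
        assert res.method == "kruskal"

    def test_single_group_error(self):
        with pytest.raises(ParameterError):
            group_burden_compare([1, 2], ["a", "a"])


class TestIciResponse:
    def _records(self, statuses):
        return [
            IciRecord(sample_id=f"I{i}", response=r, os_months=10.0, os_event=1)
            for i, r in enumerate(statuses)
        ]

    def test_rates_and_p(self):
        recs = self._records(["CR", "PR", "PR", "PR", "PD", "SD"] + ["PR", "PD", "PD", "PD", "SD", "SD"])
        mutants = {f"I{i}" for i in range(6)}
        test, rates = ici_response_assoc(recs, mutants)
        assert rates["mutant_rate_pct"] == pytest.approx(100 * 4 / 6)
        assert rates["wildtype_rate_pct"] == pytest.approx(100 * 1 / 6)
        from tests.test_survstats import fisher_two_sided_oracle

        assert test.p == pytest.approx(fisher_two_sided_oracle(4, 2, 1, 5), abs=1e-12)

    def test_ne_excluded(self):
        recs = self._records(["CR", "NE", "PD", "PD"])
        mutants = {"I0", "I1"}
        _, rates = ici_response_assoc(recs, mutants)
        assert rates["n_mutant"] == 1  # the NE mutant dropped

    def test_all_responders_p_one(self):
        recs = self._records(["CR", "PR", "CR", "PR"])
        test, _ = ici_response_assoc(recs, {"I0", "I1"})
        assert test.p == 1.0

    def test_zero_mutants_error(self):
        recs = self._records(["CR", "PD"])
        with pytest.raises(DegenerateInputError):
            ici_response_assoc(recs, set())
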