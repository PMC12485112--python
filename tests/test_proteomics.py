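"""Hi3 quantification, CV, enrichment and EASE checks against hand
computations and brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from corona_quant.proteomics import (
    AnnotationMap,
    consistent_enrichment,
    ease_overrepresentation,
    enrichment_analysis,
    hi3_quantify,
    peptide_cv_summary,
    rank_comparison,
)
from corona_quant.synthetic import ProteomeSimConfig, gen_peptide_table


def peptide_rows(acc, intensities, condition="LNP", rep="rep1", batch="batch1"):
    return [
        (f"{acc}_p{i}", acc, condition, rep, batch, v)
        for i, v in enumerate(intensities)
    ]


def as_table(rows):
    return pd.DataFrame(
        rows,
        columns=["peptide_id", "protein_accession", "condition", "replicate_id",
                 "batch_id", "intensity"],
    )


class TestHi3:
    def test_hand_ratio(self):
        table = as_table(
            peptide_rows("STD", [1200, 1000, 800]) + peptide_rows("P1", [600, 500, 400])
        )
        ab = hi3_quantify(table, standard_accession="STD", spike_fmol=50)
        p1 = ab[ab.protein_accession == "P1"].iloc[0]
        assert p1.abundance_fmol == pytest.approx(25.0)
        assert not p1.flagged

    def test_fewer_than_three_peptides_flagged(self):
        table = as_table(
            peptide_rows("STD", [1200, 1000, 800]) + peptide_rows("P1", [300, 100])
        )
        ab = hi3_quantify(table, standard_accession="STD", spike_fmol=50)
        p1 = ab[ab.protein_accession == "P1"].iloc[0]
        assert p1.abundance_fmol == pytest.approx(10.0)
        assert p1.flagged and p1.n_peptides_used == 2

    def test_standard_self_quantifies_to_spike(self):
        table, truth = gen_peptide_table(ProteomeSimConfig(n_proteins=5, seed=3))
        ab = hi3_quantify(table, truth.standard_accession, truth.spike_fmol)
        std = ab[ab.protein_accession == truth.standard_accession]
        assert np.allclose(std.abundance_fmol, truth.spike_fmol)

    def test_top3_uses_three_most_intense(self):
        table = as_table(
            peptide_rows("STD", [1000, 1000, 1000])
            + peptide_rows("P1", [10, 20, 900, 600, 300])
        )
        ab = hi3_quantify(table, "STD", 50)
        assert ab[ab.protein_accession == "P1"].iloc[0].abundance_fmol == pytest.approx(
            50 * 600 / 1000
        )

    def test_missing_standard_names_run(self):
        table = as_table(peptide_rows("P1", [1, 2, 3]))
        with pytest.raises(ValueError, match="rep1"):
            hi3_quantify(table, "STD", 50)

    def test_peptides_missing_in_excess_replicates_excluded(self):
        rows = []
        for rep in ("rep1", "rep2", "rep3"):
            rows += peptide_rows("STD", [1000, 1000, 1000], rep=rep)
        # P1 extra peptide observed only in rep1 of 3 -> excluded everywhere
        for rep in ("rep1", "rep2", "rep3"):
            rows += peptide_rows("P1", [100, 100, 100], rep=rep)
        rows.append(("P1_extra", "P1", "LNP", "rep1", "batch1", 1e6))
        ab = hi3_quantify(as_table(rows), "STD", 50)
        p1 = ab[ab.protein_accession == "P1"]
        assert np.allclose(p1.abundance_fmol, 5.0)  # unaffected by the orphan peptide


class TestCv:
    def test_identical_replicates_have_zero_cv(self):
        rows = [(f"p0", "P1", "LNP", rep, "b1", 10.0) for rep in ("r1", "r2", "r3")]
        cv = peptide_cv_summary(as_table(rows))
        assert cv.per_peptide.cv_pct.iloc[0] == 0.0

    def test_hand_cv(self):
        rows = [("p0", "P1", "LNP", rep, "b1", v) for rep, v in
                zip(("r1", "r2", "r3"), (9.0, 10.0, 11.0))]
        cv = peptide_cv_summary(as_table(rows))
        assert cv.per_peptide.cv_pct.iloc[0] == pytest.approx(10.0)
        assert cv.median_cv_pct["LNP"] == pytest.approx(10.0)

    def test_scale_invariance(self):
        table, _ = gen_peptide_table(ProteomeSimConfig(n_proteins=4, seed=5))
        cv1 = peptide_cv_summary(table)
        scaled = table.assign(intensity=table.intensity * 7)
        cv2 = peptide_cv_summary(scaled)
        pd.testing.assert_frame_equal(cv1.per_peptide, cv2.per_peptide)

    def test_single_replicate_peptides_excluded(self):
        rows = [("p0", "P1", "LNP", "r1", "b1", 5.0),
                ("p1", "P1", "LNP", "r1", "b1", 6.0),
                ("p1", "P1", "LNP", "r2", "b1", 7.0)]
        cv = peptide_cv_summary(as_table(rows))
        assert set(cv.per_peptide.peptide_id) == {"p1"}


def abundance_table(lnp, plasma, acc="P1"):
    rows = []
    for i, v in enumerate(lnp):
        rows.append((acc, "LNP", f"r{i}", "b1", v))
    for i, v in enumerate(plasma):
        rows.append((acc, "PLASMA", f"r{i}", "b1", v))
    return pd.DataFrame(
        rows,
        columns=["protein_accession", "condition", "replicate_id", "batch_id",
                 "abundance_fmol"],
    )


class TestEnrichment:
    def test_hand_welch_example(self):
        ab = abundance_table(2.0 ** np.array([3.9, 4.0, 4.1]),
                             2.0 ** np.array([1.9, 2.0, 2.1]))
        res = enrichment_analysis(ab)
        rec = res.records.iloc[0]
        assert rec.log2_fc == pytest.approx(2.0, abs=1e-12)
        assert rec.p_value < 1e-3

    def test_identical_abundances_not_significant(self):
        ab = abundance_table([4.0, 5.0, 6.0], [4.0, 5.0, 6.0])
        res = enrichment_analysis(ab)
        rec = res.records.iloc[0]
        assert rec.log2_fc == pytest.approx(0.0)
        assert rec.cls == "not_significant"

    def test_label_swap_negates_fold_changes(self):
        table, _ = gen_peptide_table(ProteomeSimConfig(n_proteins=10, seed=8))
        ab = hi3_quantify(table)
        swapped = ab.assign(
            condition=ab.condition.map({"LNP": "PLASMA", "PLASMA": "LNP"})
        )
        r1 = enrichment_analysis(ab, exclude_accessions=["P63284"]).records
        r2 = enrichment_analysis(swapped, exclude_accessions=["P63284"]).records
        merged = r1.merge(r2, on="protein_accession", suffixes=("_a", "_b"))
        assert np.allclose(merged.log2_fc_a, -merged.log2_fc_b)
        assert np.allclose(merged.p_value_a, merged.p_value_b)

    def test_bh_against_brute_force(self):
        """BH q-values agree with a direct step-up implementation."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(3, 40))
            lnp = rng.lognormal(3, 1, (n, 3))
            plasma = lnp * rng.lognormal(0, 0.5, (n, 1))
            rows = []
            for i in range(n):
                rows.append(abundance_table(lnp[i], plasma[i], acc=f"P{i}"))
            res = enrichment_analysis(pd.concat(rows, ignore_index=True))
            rec = res.records.sort_values("p_value").reset_index(drop=True)
            p = rec.p_value.to_numpy()
            m = len(p)
            q_oracle = np.minimum.accumulate((p * m / np.arange(1, m + 1))[::-1])[::-1]
            q_oracle = np.minimum(q_oracle, 1.0)
            assert np.allclose(rec.q_value.to_numpy(), q_oracle)
            assert (rec.q_value.to_numpy() >= p - 1e-15).all()

    def test_single_condition_proteins_reported_separately(self):
        ab = pd.concat([
            abundance_table([4, 5, 6], [1, 2, 3], acc="BOTH"),
            abundance_table([4, 5, 6], [], acc="LNPONLY"),
            abundance_table([], [1, 2, 3], acc="PLASMAONLY"),
        ], ignore_index=True)
        res = enrichment_analysis(ab)
        assert res.lnp_only == ["LNPONLY"]
        assert res.plasma_only == ["PLASMAONLY"]
        assert set(res.records.protein_accession) == {"BOTH"}

    def test_zero_abundance_imputed_at_half_run_minimum(self):
        ab = pd.concat([
            abundance_table([4.0, 4.0, 4.0], [4.0, 4.0, 4.0], acc="A"),
            abundance_table([0.0, 4.0, 4.0], [4.0, 4.0, 4.0], acc="B"),
        ], ignore_index=True)
        res = enrichment_analysis(ab)
        b = res.records.set_index("protein_accession").loc["B"]
        # the zero in run (LNP, r0) becomes half of that run's min nonzero (4/2)
        assert b.log2_fc == pytest.approx(np.log2(2) * (-1) / 3, abs=1e-12)


class TestRankComparison:
    def test_monotone_and_reversed(self):
        rec = pd.DataFrame({
            "protein_accession": list("ABCDE"),
            "log2_fc": [1.0, 2.0, 3.0, 4.0, 5.0],
        })
        rel = {a: 2.0 ** fc for a, fc in zip("ABCDE", rec.log2_fc)}
        assert rank_comparison(rec, rel).spearman_rho == pytest.approx(1.0)
        rel_rev = {a: -v for a, v in rel.items()}
        assert rank_comparison(rec, rel_rev).spearman_rho == pytest.approx(-1.0)

    def test_independent_vectors_average_near_zero(self):
        rng = np.random.default_rng(0)
        rhos = []
        for _ in range(200):
            rec = pd.DataFrame({
                "protein_accession": [f"P{i}" for i in range(56)],
                "log2_fc": rng.normal(size=56),
            })
            rel = {f"P{i}": rng.uniform() for i in range(56)}
            rhos.append(rank_comparison(rec, rel).spearman_rho)
        assert abs(np.mean(rhos)) < 0.03

    def test_too_few_shared_proteins(self):
        rec = pd.DataFrame({"protein_accession": ["A", "B"], "log2_fc": [1.0, 2.0]})
        with pytest.raises(ValueError):
            rank_comparison(rec, {"A": 1.0, "B": 2.0})


class FakeResult:
    def __init__(self, enriched):
        self._e = set(enriched)

    @property
    def enriched(self):
        return self._e


class TestConsistent:
    def test_intersection(self):
        s, table = consistent_enrichment([FakeResult("ABC"), FakeResult("BCD")])
        assert s == {"B", "C"}
        counts = dict(zip(table.protein_accession, table.n_batches_enriched))
        assert counts == {"A": 1, "B": 2, "C": 2, "D": 1}

    def test_single_batch_passthrough(self):
        s, _ = consistent_enrichment([FakeResult("XY")])
        assert s == {"X", "Y"}

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            consistent_enrichment([])


def hypergeom_tail(N, K, n, a):
    """P(X >= a) for X ~ Hypergeom(N, K, n) by direct summation."""
    total = 0.0
    for x in range(a, min(K, n) + 1):
        total += math.comb(K, x) * math.comb(N - K, n - x) / math.comb(N, n)
    return total


class TestEase:
    def test_spec_table(self):
        # background 100, term 10, query 20, overlap 8 -> table (7,13,3,77)
        bg = {f"g{i}" for i in range(100)}
        term = {f"g{i}" for i in range(10)}
        query = {f"g{i}" for i in range(2, 22)}
        annotations = AnnotationMap(terms={"T": term}, background=bg)
        res = ease_overrepresentation(query, annotations)
        row = res.iloc[0]
        assert row["count"] == 8
        assert row.ease_p == pytest.approx(hypergeom_tail(100, 10, 20, 7), rel=1e-9)

    def test_zero_overlap_gives_p_one(self):
        bg = {f"g{i}" for i in range(30)}
        annotations = AnnotationMap(terms={"T": {"g0", "g1"}}, background=bg)
        res = ease_overrepresentation({"g10", "g11"}, annotations)
        assert res.iloc[0].ease_p == pytest.approx(1.0)
        assert not res.iloc[0].passed

    def test_matches_enumeration_oracle_small_backgrounds(self):
        """EASE p equals the hypergeometric tail with the overlap decremented,
        and is never smaller than the plain Fisher p, over an exhaustive sweep
        of 2x2 tables with background <= 50."""
        for N in (8, 12, 20, 50):
            bg = {f"g{i}" for i in range(N)}
            for K in (2, N // 4, N // 2):
                term = {f"g{i}" for i in range(K)}
                for n in (2, N // 3, N // 2):
                    for a in range(0, min(K, n) + 1):
                        query = {f"g{i}" for i in range(a)} | {
                            f"g{K + i}" for i in range(n - a)
                        }
                        if len(query) != n or not query <= bg:
                            continue
                        annotations = AnnotationMap(terms={"T": term}, background=bg)
                        res = ease_overrepresentation(query, annotations)
                        row = res.iloc[0]
                        assert row["count"] == a
                        expected = hypergeom_tail(N, K, n, max(a - 1, 0))
                        assert row.ease_p == pytest.approx(expected, rel=1e-9)
                        if a >= 1:
                            fisher = hypergeom_tail(N, K, n, a)
                            assert row.ease_p >= fisher - 1e-12

    def test_threshold_logic(self):
        bg = {f"g{i}" for i in range(100)}
        term = {f"g{i}" for i in range(10)}
        query = {f"g{i}" for i in range(10)} | {f"g{50 + i}" for i in range(5)}
        annotations = AnnotationMap(terms={"T": term}, background=bg)
        row = ease_overrepresentation(query, annotations).iloc[0]
        assert row["count"] == 10 and row.passed

    def test_query_outside_background_rejected(self):
        annotations = AnnotationMap(terms={}, background={"a"})
        with pytest.raises(ValueError):
            ease_overrepresentation({"zzz"}, annotations)

    def test_foreign_term_skipped_with_warning(self):
        annotations = AnnotationMap(
            terms={"BAD": {"outsider"}}, background={"a", "b"}
        )
        with pytest.warns(UserWarning, match="BAD"):
            res = ease_overrepresentation({"a"}, annotations)
        assert res.empty
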