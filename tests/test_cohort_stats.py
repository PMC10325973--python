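"""Fisher/BH machinery, enrichment scans, mutual exclusivity, oncoprints."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from canisom.cohort_stats import (
    bh_adjust,
    enrichment_scan,
    fisher_two_sided,
    oncoprint_table,
    pairwise_cooccurrence,
    percent,
)


def fisher_oracle(table):
    """Exhaustive two-sided p: sum of hypergeometric probabilities of all
    tables with the observed margins that are no more likely than observed."""
    (a, b), (c, d) = table
    n = a + b + c + d
    r1, c1 = a + b, a + c
    kmin, kmax = max(0, r1 + c1 - n), min(r1, c1)
    ks = np.arange(kmin, kmax + 1)
    pmf = hypergeom.pmf(ks, n, r1, c1)
    p_obs = hypergeom.pmf(a, n, r1, c1)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


class TestFisher:
    def test_balanced_diagonal_example(self):
        _, p, _ = fisher_two_sided([[3, 0], [0, 3]])
        assert p == pytest.approx(0.1)

    def test_no_association(self):
        _, p, _ = fisher_two_sided([[5, 5], [5, 5]])
        assert p == pytest.approx(1.0)

    def test_zero_margin_degenerate(self):
        odds, p, degenerate = fisher_two_sided([[0, 0], [3, 4]])
        assert (odds, p, degenerate) == (1.0, 1.0, True)

    def test_random_tables_match_enumeration(self):
        rng = np.random.default_rng(10)
        for _ in range(200):
            t = rng.integers(0, 12, size=(2, 2))
            if min(t.sum(0).min(), t.sum(1).min()) == 0:
                continue
            _, p, _ = fisher_two_sided(t)
            assert p == pytest.approx(fisher_oracle(t), rel=1e-9)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            fisher_two_sided([[1, -1], [0, 2]])


class TestBhAdjust:
    def test_hand_evaluated_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_all_equal_unchanged(self):
        assert bh_adjust([0.04] * 5) == pytest.approx([0.04] * 5)

    def test_general_vector_against_manual_rule(self):
        ps = [0.005, 0.009, 0.05, 0.1, 0.2, 0.9]
        m = len(ps)
        # manual step-up: adj_(i) = min_{j>=i} p_(j) * m / j, capped at 1
        order = np.argsort(ps)
        sorted_adj = [ps[j] * m / (i + 1) for i, j in enumerate(order)]
        for i in range(m - 2, -1, -1):
            sorted_adj[i] = min(sorted_adj[i], sorted_adj[i + 1])
        expected = np.empty(m)
        expected[order] = np.minimum(sorted_adj, 1.0)
        assert bh_adjust(ps) == pytest.approx(list(expected))

    def test_never_below_raw_and_monotone(self):
        rng = np.random.default_rng(11)
        ps = rng.random(50)
        adj = np.array(bh_adjust(ps))
        assert np.all(adj >= ps - 1e-12)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


def make_metadata(n, types, rng):
    ids = [f"S{i:03d}" for i in range(n)]
    tumor = rng.choice(types, size=n)
    return pd.DataFrame(
        {
            "sample_id": ids,
            "tumor_type": tumor,
            "supertype": ["sarcoma" if t.endswith("sarcoma") else "carcinoma" for t in tumor],
            "breed": rng.choice(["A", "B", "Mixed"], size=n),
            "age": rng.uniform(2, 15, size=n).round(1),
            "weight": rng.uniform(5, 60, size=n).round(1),
        }
    )


class TestEnrichmentScan:
    def test_planted_enrichment_detected(self):
        rng = np.random.default_rng(12)
        n = 300
        ids = [f"S{i:03d}" for i in range(n)]
        # one 30-sample type carries the mutation at 40%, the rest at 2%
        tumor = np.array(["target"] * 30 + ["bkg"] * 270)
        metadata = pd.DataFrame(
            {
                "sample_id": ids,
                "tumor_type": tumor,
                "supertype": np.where(tumor == "target", "carcinoma", "sarcoma"),
                "breed": rng.choice(["A", "B"], size=n),
                "age": rng.uniform(2, 15, size=n),
                "weight": rng.uniform(5, 60, size=n),
            }
        )
        mutated = [
            sid
            for sid, t in zip(ids, tumor)
            if rng.random() < (0.4 if t == "target" else 0.02)
        ]
        somatic = pd.DataFrame({"sample_id": mutated, "gene": "GENE1"})
        results = enrichment_scan(somatic, metadata)
        hits = [
            r
            for r in results
            if r.feature == "GENE1" and r.group == "target" and r.group_kind == "tumor_type"
        ]
        assert hits and hits[0].adj_p < 0.05 and hits[0].score > 0

    def test_strict_feature_and_group_thresholds(self):
        rng = np.random.default_rng(13)
        metadata = make_metadata(60, ["asarcoma", "bcarcinoma"], rng)
        # gene mutated in exactly 5 dogs -> not tested
        somatic = pd.DataFrame(
            {"sample_id": metadata["sample_id"][:5], "gene": "G5"}
        )
        assert enrichment_scan(somatic, metadata) == []

        # group with exactly 20 samples -> tumor type not tested
        meta20 = make_metadata(40, ["x"], rng).assign(
            tumor_type=["t20"] * 20 + ["rest"] * 20
        )
        somatic = pd.DataFrame(
            {"sample_id": meta20["sample_id"][:25], "gene": "G"}
        )
        results = enrichment_scan(somatic, meta20, min_group_n=20)
        assert all(r.group_kind != "tumor_type" for r in results)

    def test_antisymmetry_under_group_complement(self):
        rng = np.random.default_rng(14)
        n = 100
        ids = [f"S{i:03d}" for i in range(n)]
        in_group = set(ids[:40])
        mutated = set(rng.choice(ids, size=30, replace=False))

        def scan(group_members):
            a = len(mutated & group_members)
            b = len(group_members) - a
            c = len(mutated - group_members)
            d = n - len(group_members) - c
            odds, p, _ = fisher_two_sided([[a, b], [c, d]])
            return odds, p

        o1, p1 = scan(in_group)
        o2, p2 = scan(set(ids) - in_group)
        assert p1 == pytest.approx(p2)
        assert np.log(o1) == pytest.approx(-np.log(o2), abs=1e-9)

    def test_unknown_sample_raises(self):
        rng = np.random.default_rng(15)
        metadata = make_metadata(10, ["x"], rng)
        somatic = pd.DataFrame({"sample_id": ["GHOST"], "gene": "G"})
        with pytest.raises(ValueError, match="GHOST"):
            enrichment_scan(somatic, metadata)

    def test_exchangeable_null_fdr_controlled(self):
        rng = np.random.default_rng(16)
        n = 200
        metadata = make_metadata(n, ["asarcoma", "bsarcoma", "ccarcinoma"], rng)
        rows = []
        for gene in [f"G{i}" for i in range(12)]:
            carriers = rng.choice(metadata["sample_id"], size=25, replace=False)
            rows.append(pd.DataFrame({"sample_id": carriers, "gene": gene}))
        somatic = pd.concat(rows, ignore_index=True)
        results = enrichment_scan(somatic, metadata)
        sig = [r for r in results if r.adj_p < 0.05]
        assert len(sig) <= max(1, round(0.05 * len(results)) + 2)


class TestPairwise:
    def test_planted_exclusive_pair(self):
        ids = [f"S{i}" for i in range(30)]
        rows = [{"sample_id": s, "gene": "A"} for s in ids[:10]]
        rows += [{"sample_id": s, "gene": "B"} for s in ids[10:20]]
        somatic = pd.DataFrame(rows)
        metadata = pd.DataFrame(
            {
                "sample_id": ids,
                "tumor_type": "hsa",
                "supertype": "sarcoma",
                "breed": "A",
                "age": 8.0,
                "weight": 20.0,
            }
        )
        (res,) = pairwise_cooccurrence(somatic, metadata, ids, ["A", "B"])
        assert res.direction == "mutual_exclusion"
        assert res.table == ((0, 10), (10, 10))
        assert res.p == pytest.approx(fisher_oracle(res.table), rel=1e-9)

    def test_independent_pair_large_n_not_significant(self):
        rng = np.random.default_rng(17)
        ids = [f"S{i}" for i in range(400)]
        rows = [
            {"sample_id": s, "gene": g}
            for g in ("A", "B")
            for s in ids
            if rng.random() < 0.5
        ]
        metadata = pd.DataFrame(
            {"sample_id": ids, "tumor_type": "t", "supertype": "s",
             "breed": "A", "age": 8.0, "weight": 20.0}
        )
        (res,) = pairwise_cooccurrence(pd.DataFrame(rows), metadata, ids, ["A", "B"])
        assert res.p > 0.05

    def test_single_sample_subset_degenerate(self):
        somatic = pd.DataFrame(
            [{"sample_id": "S0", "gene": "A"}, {"sample_id": "S0", "gene": "B"}]
        )
        metadata = pd.DataFrame(
            {"sample_id": ["S0"], "tumor_type": "t", "supertype": "s",
             "breed": "A", "age": 8.0, "weight": 20.0}
        )
        (res,) = pairwise_cooccurrence(somatic, metadata, ["S0"], ["A", "B"])
        assert res.p == 1.0

    def test_absent_gene_skipped_with_warning(self, caplog):
        somatic = pd.DataFrame([{"sample_id": "S0", "gene": "A"}])
        metadata = pd.DataFrame(
            {"sample_id": ["S0", "S1"], "tumor_type": "t", "supertype": "s",
             "breed": "A", "age": 8.0, "weight": 20.0}
        )
        with caplog.at_level("WARNING"):
            results = pairwise_cooccurrence(somatic, metadata, None, ["A", "ZZZ"])
        assert results == [] and "ZZZ" in caplog.text


class TestOncoprint:
    METADATA = pd.DataFrame(
        {
            "sample_id": ["S1", "S2", "S3"],
            "tumor_type": ["hsa", "hsa", "ost"],
            "supertype": ["sarcoma"] * 3,
            "breed": ["A"] * 3,
            "age": [8.0] * 3,
            "weight": [20.0] * 3,
        }
    )

    def test_single_sample_single_mutation(self):
        somatic = pd.DataFrame(
            [{"sample_id": "S1", "gene": "TP53", "mutation_class": "substitution"}]
        )
        meta = self.METADATA.iloc[:1]
        matrix, summary = oncoprint_table(somatic, meta)
        assert matrix.loc["S1", "TP53"] == "substitution"
        assert summary.loc[0, "frequency"] == 1.0

    def test_frequencies_equal_nonzero_counts(self):
        somatic = pd.DataFrame(
            [
                {"sample_id": "S1", "gene": "TP53", "mutation_class": "substitution"},
                {"sample_id": "S2", "gene": "TP53", "mutation_class": "truncation"},
                {"sample_id": "S2", "gene": "PIK3CA", "mutation_class": "substitution"},
            ]
        )
        matrix, summary = oncoprint_table(somatic, self.METADATA)
        counts = (matrix[["TP53", "PIK3CA"]] != "").sum()
        by_gene = summary.set_index("gene")
        for gene in ("TP53", "PIK3CA"):
            assert by_gene.loc[gene, "n_mutated"] == counts[gene]
            assert by_gene.loc[gene, "frequency"] == counts[gene] / 3

    def test_multi_hit_marked_and_sorted(self):
        somatic = pd.DataFrame(
            [
                {"sample_id": "S1", "gene": "TP53", "mutation_class": "substitution"},
                {"sample_id": "S1", "gene": "TP53", "mutation_class": "truncation"},
                {"sample_id": "S2", "gene": "TP53", "mutation_class": "substitution"},
                {"sample_id": "S3", "gene": "ARID1A", "mutation_class": "in_frame_indel"},
            ]
        )
        matrix, summary = oncoprint_table(somatic, self.METADATA)
        assert matrix.loc["S1", "TP53"] == "multi_hit"
        assert list(summary["gene"]) == ["TP53", "ARID1A"]

    def test_top_gene_matches_generator(self, default_cohort):
        from canisom import variant_io
        from canisom.classify import classified_by_sample, run_pipeline

        passing, _ = variant_io.qc_filter(default_cohort.calls)
        classified, _ = run_pipeline(
            passing,
            default_cohort.germline_db,
            default_cohort.human_db,
            default_cohort.codon_map,
        )
        by_sample = classified_by_sample(classified)
        somatic = by_sample[by_sample["rollup"] == "somatic"]
        _, summary = oncoprint_table(somatic, default_cohort.metadata)
        # generator truth: most-carried somatic gene by distinct samples
        truth = default_cohort.truth
        som = truth[truth["latent_class"] == "somatic"]
        keys = {
            (r.chrom, r.pos, r.ref, r.alt): None for r in som.itertuples()
        }
        gene_of = {}
        for c in default_cohort.calls:
            if (c.chrom, c.pos, c.ref, c.alt) in keys and c.gene:
                gene_of.setdefault((c.chrom, c.pos, c.ref, c.alt), c.gene)
        carriers = {}
        for r in som.itertuples():
            g = gene_of.get((r.chrom, r.pos, r.ref, r.alt))
            if g:
                carriers.setdefault(g, set()).add(r.sample_id)
        top_truth = max(carriers, key=lambda g: len(carriers[g]))
        assert summary["gene"].iloc[0] == top_truth


def test_percent_rounding():
    assert percent(151, 671, decimals=1) == 22.5
    assert percent(21, 96) == 22
    assert percent(37, 129) == 29
    with pytest.raises(ValueError):
        percent(1, 0)
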