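"""Spearman correlations, Stouffer meta-analysis, windows, and enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from triplexscan.enrichment import (
    ExpressionCohort,
    correlate_pairs,
    enrichment,
    gene_window_sites,
    meta_combine,
    meta_table,
    run_enrichment,
    spearman,
)
from triplexscan.simulate import ExpressionSimSpec, simulate_cohorts


def _cohort(seed, n=40, n_genes=6, n_mirnas=4):
    rng = np.random.default_rng(seed)
    samples = [f"s{i}" for i in range(n)]
    genes = pd.DataFrame(
        rng.normal(size=(n, n_genes)), index=samples,
        columns=[f"g{j}" for j in range(n_genes)],
    )
    mirnas = pd.DataFrame(
        rng.normal(size=(n, n_mirnas)), index=samples,
        columns=[f"m{j}" for j in range(n_mirnas)],
    )
    return ExpressionCohort("c", genes, mirnas)


class TestSpearman:
    def test_monotone_increasing_is_plus_one(self):
        x = np.arange(10.0)
        rho, p = spearman(x, np.exp(x))
        assert rho == pytest.approx(1.0)

    def test_reverse_ranked_is_minus_one(self):
        x = np.arange(10.0)
        rho, _ = spearman(x, -(x**3))
        assert rho == pytest.approx(-1.0)

    def test_tied_data_matches_rank_formula(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 5, size=20).astype(float)  # heavy ties
        y = rng.integers(0, 5, size=20).astype(float)
        rho, _ = spearman(x, y)
        # exhaustive oracle: Pearson product-moment of average ranks
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_flagged(self):
        rho, p = spearman(np.ones(10), np.arange(10.0))
        assert np.isnan(rho) and np.isnan(p)

    def test_short_vectors_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 2], [3, 4])


class TestCorrelatePairs:
    def test_matches_per_pair_spearman(self):
        cohort = _cohort(11)
        pairs = [("m0", "g0"), ("m1", "g3"), ("m3", "g5")]
        table = correlate_pairs(cohort, pairs)
        for row in table.itertuples():
            rho, p = spearman(
                cohort.mirnas[row.mirna_id], cohort.genes[row.gene_id]
            )
            assert row.rho == pytest.approx(rho, abs=1e-12)
            assert row.p == pytest.approx(p, abs=1e-12, rel=1e-9)

    def test_constant_gene_flagged_invalid(self):
        cohort = _cohort(12)
        cohort.genes["g0"] = 5.0
        table = correlate_pairs(cohort, [("m0", "g0"), ("m0", "g1")])
        assert not table[table.gene_id == "g0"].valid.iloc[0]
        assert table[table.gene_id == "g1"].valid.iloc[0]

    def test_unknown_identifier_rejected(self):
        with pytest.raises(KeyError):
            correlate_pairs(_cohort(13), [("nope", "g0")])


class TestMetaCombine:
    def test_concordant_evidence_sharpens(self):
        meta_p, direction = meta_combine([0.4, 0.5], [0.05, 0.05])
        assert meta_p < 0.05 and direction == 1

    def test_single_cohort_identity(self):
        for rho, p in [(0.4, 0.03), (-0.2, 0.6)]:
            meta_p, direction = meta_combine([rho], [p])
            assert meta_p == pytest.approx(p, rel=1e-9)
            assert direction == (1 if rho > 0 else -1)

    def test_closed_form_two_cohorts(self):
        z = stats.norm.isf(np.array([0.01, 0.015]))  # one-sided 0.02/2, 0.03/2
        expected = 2 * stats.norm.sf(abs(z.sum() / np.sqrt(2)))
        meta_p, direction = meta_combine([0.3, 0.2], [0.02, 0.03])
        assert meta_p == pytest.approx(expected, rel=1e-12)
        assert direction == 1

    def test_matches_scipy_stouffer_for_positive_directions(self):
        pvals = np.array([0.02, 0.2, 0.07])
        ref = stats.combine_pvalues(pvals / 2, method="stouffer").pvalue
        meta_p, _ = meta_combine([0.5, 0.3, 0.4], pvals)
        assert meta_p / 2 == pytest.approx(ref, rel=1e-9)

    def test_opposite_extremes_cancel(self):
        meta_p, _ = meta_combine([0.9, -0.9], [1e-8, 1e-8])
        assert meta_p > 0.9

    def test_cohort_order_invariant(self):
        a = meta_combine([0.5, -0.1, 0.2], [0.01, 0.8, 0.2])
        b = meta_combine([0.2, 0.5, -0.1], [0.2, 0.01, 0.8])
        assert a == b

    def test_all_undefined_rejected(self):
        with pytest.raises(ValueError):
            meta_combine([np.nan], [np.nan])


class TestGeneWindow:
    def _frames(self, site_ivals, gene_ivals):
        sites = pd.DataFrame(
            [
                {"chrom": "c", "start": s, "end": e, "strand": "+",
                 "mirna_id": f"m{i}", "grade": 1}
                for i, (s, e) in enumerate(site_ivals)
            ]
        )
        genes = pd.DataFrame(
            [
                {"chrom": "c", "start": s, "end": e, "gene_id": f"g{i}", "strand": "+"}
                for i, (s, e) in enumerate(gene_ivals)
            ]
        )
        return sites, genes

    def test_window_boundaries(self):
        gene = (20_000, 22_000)
        cases = {
            (14_980, 15_001): True,   # ends 4999 bp upstream of gene start
            (27_001, 27_030): False,  # starts 5001 bp downstream of gene end
            (27_000, 27_030): True,   # gap of exactly 5000 is inclusive
            (20_500, 20_530): True,   # inside the gene body
        }
        for ival, expected in cases.items():
            sites, genes = self._frames([ival], [gene])
            assoc = gene_window_sites(sites, genes, window=5000)
            assert (len(assoc) == 1) is expected, ival

    def test_random_placements_match_double_loop_oracle(self):
        rng = np.random.default_rng(21)
        site_ivals = [(int(s), int(s) + 30) for s in rng.integers(0, 10**6, 150)]
        gene_ivals = [(int(s), int(s) + 2000) for s in rng.integers(0, 10**6, 40)]
        sites, genes = self._frames(site_ivals, gene_ivals)
        assoc = gene_window_sites(sites, genes, window=5000)
        got = set(zip(assoc.gene_id, assoc.mirna_id))
        expected = set()
        for gi, (gs, ge) in enumerate(gene_ivals):
            for si, (ss, se) in enumerate(site_ivals):
                gap = max(0, gs - se, ss - ge)
                if gap <= 5000:
                    expected.add((f"g{gi}", f"m{si}"))
        assert got == expected

    def test_only_requested_grades_count(self):
        sites, genes = self._frames([(1000, 1030)], [(2000, 3000)])
        sites.loc[0, "grade"] = 3
        assert gene_window_sites(sites, genes).empty
        assert len(gene_window_sites(sites, genes, grades=(1, 2, 3))) == 1


def _planted_run(seed, n_assoc=80, n_planted=40, rho=0.5, n_samples=60):
    spec = ExpressionSimSpec(
        n_samples=(n_samples, n_samples), n_genes=n_assoc, n_mirnas=8
    )
    gids, mids = spec.gene_ids(), spec.mirna_ids()
    spec.planted_pairs = [
        (mids[i % 8], gids[i], rho) for i in range(n_planted)
    ]
    spec.__post_init__()
    c1, c2, _ = simulate_cohorts(spec, seed)
    sites = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": [i * 20_000 for i in range(n_assoc)],
            "end": [i * 20_000 + 30 for i in range(n_assoc)],
            "strand": "+",
            "mirna_id": [mids[i % 8] for i in range(n_assoc)],
            "grade": 1,
        }
    )
    genes = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": [i * 20_000 + 2_000 for i in range(n_assoc)],
            "end": [i * 20_000 + 4_000 for i in range(n_assoc)],
            "gene_id": gids,
            "strand": "+",
        }
    )
    return sites, genes, (c1, c2)


class TestEnrichment:
    def test_printed_count_fold(self):
        records = pd.DataFrame(
            {
                "mirna_id": ["m"] * 300,
                "gene_id": [f"g{i}" for i in range(300)],
                "meta_p": [0.001] * 268 + [0.5] * 32,
                "direction": [1] * 206 + [-1] * 62 + [1] * 32,
            }
        )
        assoc = pd.DataFrame(
            {"mirna_id": ["m"] * 300, "gene_id": [f"g{i}" for i in range(300)],
             "chrom": "c", "site_start": 0, "site_end": 30}
        )
        result = enrichment(records, assoc, alpha=0.01)
        assert (result.n_positive, result.n_negative) == (206, 62)
        assert round(result.fold, 1) == 3.3
        assert result.test_p < 1e-15

    def test_equal_counts_fold_one(self):
        records = pd.DataFrame(
            {
                "mirna_id": ["m"] * 20,
                "gene_id": [f"g{i}" for i in range(20)],
                "meta_p": [0.001] * 20,
                "direction": [1] * 10 + [-1] * 10,
            }
        )
        assoc = pd.DataFrame(
            {"mirna_id": ["m"] * 20, "gene_id": [f"g{i}" for i in range(20)],
             "chrom": "c", "site_start": 0, "site_end": 30}
        )
        result = enrichment(records, assoc, alpha=0.01)
        assert result.fold == 1.0

    def test_zero_negative_flagged_infinite(self):
        records = pd.DataFrame(
            {"mirna_id": ["m"], "gene_id": ["g0"], "meta_p": [1e-4], "direction": [1]}
        )
        assoc = pd.DataFrame(
            {"mirna_id": ["m"], "gene_id": ["g0"], "chrom": "c",
             "site_start": 0, "site_end": 30}
        )
        result = enrichment(records, assoc)
        assert np.isinf(result.fold)
        assert "zero_negative_pairs" in result.flags

    def test_planted_positive_effects_recovered(self):
        sites, genes, cohorts = _planted_run(seed=5)
        records, result = run_enrichment(sites, genes, cohorts)
        assert result.fold > 1
        assert result.test_p < 0.01
        assert result.n_genes_with_grade1 == 80

    def test_permuting_sample_labels_destroys_enrichment(self):
        sites, genes, (c1, c2) = _planted_run(seed=6)
        rng = np.random.default_rng(0)

        def shuffled(c, name):
            # permute the gene rows relative to their sample labels, so the
            # label-based alignment cannot undo the break
            perm = rng.permutation(len(c.genes))
            genes = pd.DataFrame(
                c.genes.to_numpy()[perm], index=c.genes.index, columns=c.genes.columns
            )
            return ExpressionCohort(name, genes, c.mirnas)

        folds = []
        for _ in range(5):
            perm1 = shuffled(c1, "p1")
            perm2 = shuffled(c2, "p2")
            _, result = run_enrichment(sites, genes, [perm1, perm2])
            folds.append((result.n_positive, result.n_negative))
        # with the miRNA-gene link broken, significant pairs all but vanish
        assert sum(p + n for p, n in folds) <= 10
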