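import numpy as np
import pandas as pd
import pytest

from oracles import exact_ranksum_p
from pd1sig import (
    CellMatrix,
    ExpressionMatrix,
    GeneSignature,
    PipelineConfig,
    assemble_candidates,
    build_signature,
    filter_deg,
    find_cluster_markers,
    identify_top_cluster,
    percentile_expression_filter,
    qc_filter_cells,
    refine_signature,
    scan_percentile_cutoffs,
    simulate_scrna,
    tumor_expression_filter,
)


def tpm_matrix(values, genes, samples=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes,
                                         columns=samples), unit="TPM")


class TestDegFilter:
    def test_both_rules_applied(self):
        de = pd.DataFrame(
            {
                "gene": ["a", "b", "c", "d"],
                "log2fc": [1.5, 3.0, 0.5, -1.2],
                "padj": [0.01, 0.2, 0.001, 0.04],
            }
        )
        assert filter_deg(de) == ["a", "d"]

    def test_boundaries_are_strict(self):
        de = pd.DataFrame(
            {
                "gene": ["at_p", "at_fc", "ok"],
                "log2fc": [2.0, 1.0, 1.5],
                "padj": [0.05, 0.01, 0.01],
            }
        )
        assert filter_deg(de) == ["ok"]


class TestCandidates:
    def test_union_dedup_sorted(self):
        sig = assemble_candidates(["B", "A"], ["B", "C"])
        assert sig.genes == ["A", "B", "C"]
        assert sig.stage == "candidate"

    def test_disjoint_sizes_add(self):
        assert len(assemble_candidates(["a", "b", "c"], ["d", "e"])) == 5

    def test_idempotent(self):
        assert assemble_candidates(["x", "y"], ["x", "y"]).genes == ["x", "y"]


class TestTumorFilter:
    def _lines(self, medians_log2):
        # constant rows make the median exact
        tpm = {g: 2.0**m - 1.0 for g, m in medians_log2.items()}
        return tpm_matrix(
            [[v] * 5 for v in tpm.values()], list(tpm.keys())
        )

    def test_high_and_low_and_boundary(self):
        lines = self._lines({"hi": 3.5, "lo": 0.2, "edge": 3.1})
        sig = GeneSignature(["hi", "lo", "edge"], stage="candidate")
        out = tumor_expression_filter(sig, lines)
        assert out.genes == ["lo"]  # "below 3.1" is strict; 3.5 and 3.1 drop

    def test_absent_genes_retained_with_warning(self):
        lines = self._lines({"lo": 0.2})
        sig = GeneSignature(["lo", "ghost"], stage="candidate")
        with pytest.warns(UserWarning, match="absent"):
            out = tumor_expression_filter(sig, lines)
        assert "ghost" in out.genes


class TestPercentileFilter:
    def test_keeps_top_sixty_percent(self):
        genes = [f"g{i}" for i in range(10)]
        x = tpm_matrix([[10 - i] * 3 for i in range(10)], genes)
        out = percentile_expression_filter(GeneSignature(genes), x, 0.6)
        assert sorted(out.genes) == sorted(genes[:6])

    def test_keep_all_is_identity(self):
        genes = ["a", "b", "c"]
        x = tpm_matrix([[1] * 2, [2] * 2, [3] * 2], genes)
        out = percentile_expression_filter(GeneSignature(genes), x, 1.0)
        assert sorted(out.genes) == genes

    def test_boundary_tie_broken_lexicographically(self):
        # means (5,4,3,3,1); keep 0.6 of 5 -> 3: top two plus the
        # lexicographically first of the tied pair
        genes = ["e", "d", "c", "b", "a"]
        x = tpm_matrix([[5], [4], [3], [3], [1]], genes)
        out = percentile_expression_filter(GeneSignature(genes), x, 0.6)
        assert sorted(out.genes) == ["b", "d", "e"]


class TestCutoffScan:
    def _two_class(self, seed=0):
        # candidate genes whose mean ordering interleaves shifted and
        # unshifted genes (base spacing 2^5 exceeds the 2^4 shift), so
        # every scanned subset mixes both kinds and can separate classes
        rng = np.random.default_rng(seed)
        genes = [f"g{i:02d}" for i in range(15)]
        base = 2.0 ** (70.0 - 5.0 * np.arange(15))
        shifted = [g for i, g in enumerate(genes) if i % 2 == 0]
        samples = [f"s{i}" for i in range(10)]
        labels = pd.Series([i < 5 for i in range(10)], index=samples)
        values = np.tile(base[:, None], (1, 10))
        values *= 2.0 ** rng.normal(0, 0.1, values.shape)
        idx = [genes.index(g) for g in shifted]
        values[np.ix_(idx, np.where(labels)[0])] *= 2.0**4
        x = tpm_matrix(values, genes, samples)
        return GeneSignature(genes), x, labels

    def test_grid_default_and_smallest_sufficient_fraction(self):
        sig, x, labels = self._two_class()
        chosen, report = scan_percentile_cutoffs(sig, x, labels)
        assert list(report["fraction"]) == [0.2, 0.4, 0.6, 0.8]
        assert report["perfect"].all()
        assert chosen == 0.2

    def test_single_class_rejected(self):
        sig, x, labels = self._two_class()
        with pytest.raises(ValueError, match="both classes"):
            scan_percentile_cutoffs(sig, x, pd.Series(True, index=x.samples))


class TestCellQC:
    def _cells(self, detected, mito_frac, n_genes=6000):
        """One cell per (detected, mito_frac) spec."""
        cols = {}
        genes = [f"MT-{i}" for i in range(10)] + [
            f"g{i}" for i in range(n_genes - 10)
        ]
        for i, (d, m) in enumerate(zip(detected, mito_frac)):
            v = np.zeros(n_genes)
            body = max(d - 10, 0)
            v[10:10 + body] = 19.0  # 19 counts/gene keeps 5% mito integral
            total_body = body * 19.0
            mito_total = m / (1 - m) * total_body if m > 0 else 0.0
            v[:10] = np.floor(mito_total / 10.0)
            cols[f"c{i}"] = v
        df = pd.DataFrame(cols, index=genes)
        return CellMatrix(df, unit="counts")

    def test_window_and_mito_rules(self):
        cells = self._cells(
            detected=[500, 3000, 3000, 5500],
            mito_frac=[0.0, 0.02, 0.10, 0.0],
        )
        kept = qc_filter_cells(cells, PipelineConfig())
        assert kept.cells == ["c1"]

    def test_mito_boundary_is_strict(self):
        cells = self._cells(detected=[3000, 3000], mito_frac=[0.0, 0.05])
        kept = qc_filter_cells(cells, PipelineConfig())
        assert kept.cells == ["c0"]

    def test_all_cells_removed_rejected(self):
        cells = self._cells(detected=[100], mito_frac=[0.0])
        with pytest.raises(ValueError, match="every cell"):
            qc_filter_cells(cells, PipelineConfig())


class TestMarkers:
    def _cells_with_gene(self, in_vals, out_vals, filler_seed=0):
        rng = np.random.default_rng(filler_seed)
        n_in, n_out = len(in_vals), len(out_vals)
        filler = rng.poisson(5.0, size=(20, n_in + n_out))
        values = np.vstack([np.concatenate([in_vals, out_vals]), filler])
        genes = ["target"] + [f"f{i}" for i in range(20)]
        cells = [f"c{i}" for i in range(n_in + n_out)]
        clusters = pd.Series(["in"] * n_in + ["out"] * n_out, index=cells)
        df = pd.DataFrame(values, index=genes, columns=cells)
        return CellMatrix(df, unit="counts", clusters=clusters)

    def test_perfectly_separated_gene_is_marker(self):
        cells = self._cells_with_gene([50] * 8, [0] * 8)
        table = find_cluster_markers(cells, "in")
        row = table[table["gene"] == "target"].iloc[0]
        assert row["logfc"] > 0.25
        assert row["p"] < 0.01
        assert row["frac_in"] == 1.0 and row["frac_out"] == 0.0

    def test_rarely_expressed_gene_excluded(self):
        # expressed in 10% of cells on both sides: below the 25% rule
        in_vals = [100] + [0] * 9
        out_vals = [100] + [0] * 9
        cells = self._cells_with_gene(in_vals, out_vals)
        table = find_cluster_markers(cells, "in")
        assert "target" not in set(table["gene"])

    def test_wilcoxon_p_matches_exact_enumeration(self):
        # 6 vs 6 cells, distinct values -> scipy uses the exact null;
        # compare against full enumeration over group assignments
        in_vals = [12, 25, 31, 44, 58, 66]
        out_vals = [3, 8, 15, 22, 29, 35]
        cells = self._cells_with_gene(in_vals, out_vals)
        table = find_cluster_markers(cells, "in")
        row = table[table["gene"] == "target"].iloc[0]
        # normalization is monotone per cell only if depths are equal;
        # use the raw values for the oracle on the rank scale
        norm = np.log1p(
            np.array(in_vals + out_vals)
            / cells.values.sum(axis=0).to_numpy() * 1e4
        )
        expected = exact_ranksum_p(norm[:6], norm[6:])
        assert row["p"] == pytest.approx(expected, abs=1e-12)

    def test_degenerate_cluster_rejected(self):
        cells = self._cells_with_gene([5, 5], [5] * 8)
        with pytest.raises(ValueError, match="3 cells"):
            find_cluster_markers(cells, "in")


class TestTopCluster:
    def test_highest_mean_wins(self):
        scores = pd.Series([0.8, 0.8, 0.3, 0.3], index=list("abcd"))
        labels = pd.Series(["x", "x", "y", "y"], index=list("abcd"))
        top, margin = identify_top_cluster(scores, labels)
        assert top == "x" and margin == pytest.approx(0.5)

    def test_three_clusters(self):
        scores = pd.Series([0.2, 0.5, 0.9], index=list("abc"))
        labels = pd.Series(["u", "v", "w"], index=list("abc"))
        assert identify_top_cluster(scores, labels)[0] == "w"

    def test_tie_demands_review(self):
        scores = pd.Series([0.4, 0.4], index=list("ab"))
        labels = pd.Series(["x", "y"], index=list("ab"))
        with pytest.raises(ValueError, match="tie"):
            identify_top_cluster(scores, labels)

    def test_recovers_spiked_cluster_in_simulation(self):
        from pd1sig import GeneSignature, compute_background, rank_score

        cells, truth = simulate_scrna(spike_factor=4.0, seed=11)
        tpm = cells.to_tpm()
        bg = compute_background(tpm)
        sig = GeneSignature(truth.signature_genes)
        scores = rank_score(tpm, sig, bg)["score"]
        top, _ = identify_top_cluster(scores, truth.cell_cluster)
        assert top == f"c{truth.params['spiked_cluster']}"


class TestRefine:
    def _markers(self, genes, logfc=1.0):
        return pd.DataFrame(
            {"gene": genes, "logfc": logfc, "p": 1e-5,
             "frac_in": 0.9, "frac_out": 0.1}
        )

    def test_intersection(self):
        initial = GeneSignature(["A", "B", "C"], stage="initial")
        out = refine_signature(initial, self._markers(["B", "C", "D"]))
        assert out.genes == ["B", "C"] and out.stage == "final"

    def test_superset_markers_identity(self):
        initial = GeneSignature(["A", "B"], stage="initial")
        out = refine_signature(initial, self._markers(["A", "B", "Z"]))
        assert out.genes == ["A", "B"]

    def test_downregulated_markers_ignored(self):
        initial = GeneSignature(["A", "B"], stage="initial")
        markers = pd.concat(
            [self._markers(["A"]), self._markers(["B"], logfc=-1.0)]
        )
        assert refine_signature(initial, markers).genes == ["A"]

    def test_published_core_is_a_known_subset(self):
        from pd1sig.gene_sets import pd1hi_core

        core = pd1hi_core()
        assert len(core) == 14
        assert {"PDCD1", "CTLA4", "TOX", "RAD51"} <= set(core.genes)


class TestPipeline:
    def test_monotone_shrinkage(self, built_signature):
        res = built_signature
        assert set(res.final.genes) <= set(res.initial.genes)
        assert set(res.initial.genes) <= set(res.candidate.genes)

    def test_stage_tags(self, built_signature):
        assert built_signature.candidate.stage == "candidate"
        assert built_signature.initial.stage == "initial"
        assert built_signature.final.stage == "final"

    def test_deterministic_rerun(self, construction_fixture, built_signature):
        fx = construction_fixture
        deg = filter_deg(fx.de_table)
        again = build_signature(
            fx.cd8_specific, deg, fx.lines, fx.pd1hi_expr, fx.cells,
            cd8_expr=fx.cd8_expr, cd8_labels=fx.cd8_labels,
        )
        assert again.final.genes == built_signature.final.genes
        assert again.audit == built_signature.audit
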