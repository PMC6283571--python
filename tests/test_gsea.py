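import numpy as np
import pandas as pd
import pytest

import immunoscape as im
from immunoscape.gsea import _es_from_positions


def brute_force_es(genes, metric, gene_set, weight):
    """Second, position-by-position implementation of the running sum."""
    order = sorted(range(len(genes)), key=lambda i: (-metric[i], genes[i]))
    hits = [genes[i] in set(gene_set) for i in order]
    nh = sum(hits)
    wsum = sum(abs(metric[order[j]]) ** weight for j in range(len(genes)) if hits[j])
    running, cur = [], 0.0
    for j in range(len(genes)):
        if hits[j]:
            cur += (abs(metric[order[j]]) ** weight) / wsum if wsum > 0 else 1.0 / nh
        else:
            cur -= 1.0 / (len(genes) - nh)
        running.append(cur)
    top, bottom = max(running), min(running)
    return top if top >= -bottom else bottom


class TestSignalToNoise:
    def _expr(self, rows, samples):
        genes = [f"g{i}" for i in range(len(rows))]
        return im.ExpressionMatrix(genes, samples, np.asarray(rows, float))

    def test_identical_distributions_give_zero(self):
        expr = self._expr([[2, 3, 2, 3], [1, 1, 1, 1]], list("wxyz"))
        ranked = im.signal_to_noise(expr, ["w", "x"], ["y", "z"])
        assert (ranked["metric"] == 0).all()

    def test_sd_floor_worked_example(self):
        # x {3,5}, y {1,1}: (4-1)/(sqrt(2) + 0.2) with the 0.2*|mean| floor on y
        expr = self._expr([[3, 5, 1, 1], [9, 9, 9, 9]], list("wxyz"))
        ranked = im.signal_to_noise(expr, ["w", "x"], ["y", "z"]).set_index("gene_id")
        assert ranked.loc["g0", "metric"] == pytest.approx(3 / (np.sqrt(2) + 0.2))

    def test_absolute_floor_at_zero_mean(self):
        expr = self._expr([[1, 3, 0, 0], [5, 5, 5, 5]], list("wxyz"))
        ranked = im.signal_to_noise(expr, ["w", "x"], ["y", "z"]).set_index("gene_id")
        # y group mean 0 -> sd floored at 0.2
        assert ranked.loc["g0", "metric"] == pytest.approx(2 / (np.sqrt(2) + 0.2))

    def test_swapping_groups_negates_and_reverses(self):
        rng = np.random.default_rng(0)
        expr = self._expr(rng.uniform(1, 9, size=(20, 6)), [f"s{i}" for i in range(6)])
        fwd = im.signal_to_noise(expr, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        rev = im.signal_to_noise(expr, ["s3", "s4", "s5"], ["s0", "s1", "s2"])
        merged = fwd.set_index("gene_id")["metric"] + rev.set_index("gene_id")["metric"]
        np.testing.assert_allclose(merged.to_numpy(), 0.0, atol=1e-12)
        assert list(fwd["gene_id"]) == list(rev["gene_id"])[::-1] or (fwd["metric"] == 0).any() is False

    def test_small_group_rejected(self):
        expr = self._expr([[1, 2, 3], [3, 2, 1]], list("xyz"))
        with pytest.raises(ValueError, match=">= 2 samples"):
            im.signal_to_noise(expr, ["x"], ["y", "z"])


class TestEnrichmentScore:
    def _ranked(self, n=10, seed=1):
        rng = np.random.default_rng(seed)
        metric = np.sort(rng.normal(size=n))[::-1]
        return pd.DataFrame({"gene_id": [f"g{i:02d}" for i in range(n)], "metric": metric})

    def test_single_top_gene_weight_one(self):
        ranked = self._ranked()
        top = ranked["gene_id"].iloc[0]
        es, running, peak, leading = im.enrichment_score(ranked, [top], weight=1.0)
        assert es == pytest.approx(1.0)
        assert peak == 0
        assert leading == [top]

    def test_single_bottom_gene_negative_es(self):
        ranked = pd.DataFrame({"gene_id": [f"g{i}" for i in range(6)],
                               "metric": [6.0, 5.0, 4.0, 3.0, 2.0, 1.0]})
        es, _, _, leading = im.enrichment_score(ranked, ["g5"], weight=1.0)
        assert es < 0
        assert leading == ["g5"]

    def test_es_bounded(self):
        rng = np.random.default_rng(2)
        ranked = self._ranked(50, seed=2)
        for _ in range(10):
            k = int(rng.integers(1, 25))
            gene_set = list(rng.choice(ranked["gene_id"], k, replace=False))
            es, _, _, _ = im.enrichment_score(ranked, gene_set)
            assert -1.0 <= es <= 1.0

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(3)
        ranked = self._ranked(100, seed=3)
        genes = list(ranked["gene_id"])
        metric = ranked["metric"].to_numpy()
        for _ in range(10):
            gene_set = list(rng.choice(genes, 10, replace=False))
            es, _, _, _ = im.enrichment_score(ranked, gene_set, weight=1.0)
            assert es == pytest.approx(brute_force_es(genes, metric, gene_set, 1.0), rel=1e-12)

    def test_positions_shortcut_equals_full_walk(self):
        rng = np.random.default_rng(4)
        ranked = self._ranked(80, seed=4)
        metric = ranked["metric"].to_numpy()
        for _ in range(10):
            k = int(rng.integers(2, 30))
            pos = np.sort(rng.choice(80, k, replace=False))
            gene_set = list(ranked["gene_id"].iloc[pos])
            es_full, _, _, _ = im.enrichment_score(ranked, gene_set, weight=1.0)
            es_fast = _es_from_positions(pos, np.abs(metric[pos]), 80)
            assert es_fast == pytest.approx(es_full, rel=1e-12)

    def test_weight_zero_reduces_to_ks_statistic(self):
        """With weight 0 the magnitude of the ES equals the classical
        two-sample KS statistic between in-set and out-of-set rank positions."""
        from scipy.stats import ks_2samp

        rng = np.random.default_rng(5)
        ranked = self._ranked(60, seed=5)
        for _ in range(5):
            k = int(rng.integers(5, 25))
            pos = np.sort(rng.choice(60, k, replace=False))
            gene_set = list(ranked["gene_id"].iloc[pos])
            es, _, _, _ = im.enrichment_score(ranked, gene_set, weight=0.0)
            out_pos = np.setdiff1d(np.arange(60), pos)
            ks = ks_2samp(pos, out_pos).statistic
            assert abs(es) == pytest.approx(ks, rel=1e-12)

    def test_matches_external_gsea_implementation(self):
        """Cross-check the weighted ES against gseapy's preranked GSEA."""
        gseapy = pytest.importorskip("gseapy")
        rng = np.random.default_rng(6)
        genes = [f"g{i:03d}" for i in range(100)]
        metric = np.sort(rng.normal(size=100))[::-1]
        gene_set = list(rng.choice(genes, 12, replace=False))
        res = gseapy.prerank(
            rnk=pd.Series(metric, index=genes).reset_index(),
            gene_sets={"S": gene_set}, permutation_num=10, seed=1, min_size=1,
            max_size=500, threads=1, no_plot=True, outdir=None, weight=1.0,
        )
        external = float(res.res2d.set_index("Term").loc["S", "ES"])
        ranked = pd.DataFrame({"gene_id": genes, "metric": metric})
        es, _, _, _ = im.enrichment_score(ranked, gene_set, weight=1.0)
        assert es == pytest.approx(external, rel=1e-9)

    def test_degenerate_sets_rejected(self):
        ranked = self._ranked()
        with pytest.raises(ValueError):
            im.enrichment_score(ranked, ["nope"])
        with pytest.raises(ValueError):
            im.enrichment_score(ranked, list(ranked["gene_id"]))


def _two_group_matrix(seed, n_genes=300, n_per_group=20, shift_genes=(), shift=0.0):
    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    log2x = rng.normal(6, 1, size=(n_genes, 2 * n_per_group))
    for g in shift_genes:
        log2x[genes.index(g), :n_per_group] += shift
    expr = im.ExpressionMatrix(genes, [f"s{i}" for i in range(2 * n_per_group)], 2.0**log2x)
    gx = expr.sample_ids[:n_per_group]
    gy = expr.sample_ids[n_per_group:]
    return expr, gx, gy, genes


class TestGseaPermutation:
    def test_same_seed_identical(self):
        expr, gx, gy, genes = _two_group_matrix(0)
        pathways = im.GeneSetCollection({"P1": genes[:15], "P2": genes[20:40]})
        r1 = im.gsea_permutation(expr, gx, gy, pathways, n_perm=100, seed=9)
        r2 = im.gsea_permutation(expr, gx, gy, pathways, n_perm=100, seed=9)
        for a, b in zip(r1, r2):
            assert (a.es, a.nes, a.nominal_p, a.fdr, a.leading_edge) == (
                b.es, b.nes, b.nominal_p, b.fdr, b.leading_edge
            )

    def test_null_data_rarely_significant(self):
        hits, total = 0, 0
        for seed in range(4):
            expr, gx, gy, genes = _two_group_matrix(seed + 10)
            pathways = im.GeneSetCollection(
                {f"P{j}": genes[15 * j : 15 * (j + 1)] for j in range(8)}
            )
            res = im.gsea_permutation(expr, gx, gy, pathways, n_perm=100, seed=seed)
            hits += sum(r.fdr <= 0.05 for r in res)
            total += len(res)
        assert hits / total <= 0.1

    def test_embedded_pathway_attains_top_nes_and_low_fdr(self):
        recovered = 0
        n_rep = 10
        for seed in range(n_rep):
            shift_genes = [f"g{i:04d}" for i in range(15)]
            expr, gx, gy, genes = _two_group_matrix(seed + 50, shift_genes=shift_genes, shift=1.2)
            pathways = im.GeneSetCollection(
                {"SHIFT": genes[:15], **{f"P{j}": genes[15 * j : 15 * (j + 1)] for j in range(2, 6)}}
            )
            res = im.gsea_permutation(expr, gx, gy, pathways, n_perm=100, seed=seed)
            by_name = {r.pathway: r for r in res}
            top = max(res, key=lambda r: r.nes)
            recovered += top.pathway == "SHIFT" and by_name["SHIFT"].fdr <= 0.05
        assert recovered >= 9

    def test_leading_edge_subset_of_pathway(self):
        expr, gx, gy, genes = _two_group_matrix(99, shift_genes=[f"g{i:04d}" for i in range(10)], shift=1.0)
        pathways = im.GeneSetCollection({"SHIFT": genes[:10], "OTHER": genes[30:60]})
        for r in im.gsea_permutation(expr, gx, gy, pathways, n_perm=100, seed=1):
            assert set(r.leading_edge) <= set(pathways[r.pathway])
            assert -1 <= r.es <= 1
            assert np.sign(r.nes) == np.sign(r.es) or r.es == 0
            assert 0 <= r.fdr <= 1
            assert r.nominal_p >= 1 / 100

    def test_pathway_without_genes_skipped(self, caplog):
        expr, gx, gy, genes = _two_group_matrix(7)
        pathways = im.GeneSetCollection({"EMPTYISH": ["zz1", "zz2"], "OK": genes[:10]})
        with caplog.at_level("WARNING", logger="immunoscape.gsea"):
            res = im.gsea_permutation(expr, gx, gy, pathways, n_perm=100, seed=0)
        assert [r.pathway for r in res] == ["OK"]


class TestDeltaNesSelect:
    @staticmethod
    def _published_frames():
        t4 = im.published_pathway_table()
        ca = t4.rename(columns={"nes_ca": "nes", "fdr_ca": "fdr"})[["pathway", "nes", "fdr"]]
        da = t4.rename(columns={"nes_da": "nes", "fdr_da": "fdr"})[["pathway", "nes", "fdr"]]
        return t4, ca, da

    def test_apoptosis_delta(self):
        _, ca, da = self._published_frames()
        out = im.delta_nes_select(ca, da).set_index("pathway")
        assert out.loc["Apoptosis", "delta"] == pytest.approx(0.49)

    def test_equal_nes_not_selected(self):
        frame = pd.DataFrame({"pathway": ["X"], "nes": [2.0], "fdr": [0.01]})
        out = im.delta_nes_select(frame, frame)
        assert not out["selected"].iloc[0]
        assert out["delta"].iloc[0] == 0.0

    def test_published_selection_yields_the_five_named_pathways(self):
        _, ca, da = self._published_frames()
        out = im.delta_nes_select(ca, da, fdr_max=0.05, delta_min=0.25)
        assert len(out) == 12  # all rows pass the C-vs-A FDR gate
        selected = set(out.loc[out["selected"], "pathway"])
        assert selected == {
            "Apoptosis",
            "TNF-a signaling via NF-kB",
            "Apical surface",
            "Interferon-a response",
            "KRAS signaling upregulation",
        }

    def test_recomputed_deltas_match_printed_within_rounding(self):
        t4, ca, da = self._published_frames()
        out = im.delta_nes_select(ca, da).set_index("pathway")
        for _, row in t4.iterrows():
            assert out.loc[row["pathway"], "delta"] == pytest.approx(
                row["printed_delta"], abs=0.0101
            )

    def test_unmatched_pathway_excluded_with_warning(self, caplog):
        ca = pd.DataFrame({"pathway": ["X", "Y"], "nes": [2.0, 1.5], "fdr": [0.01, 0.01]})
        da = pd.DataFrame({"pathway": ["X"], "nes": [1.0], "fdr": [0.2]})
        with caplog.at_level("WARNING", logger="immunoscape.gsea"):
            out = im.delta_nes_select(ca, da)
        assert list(out["pathway"]) == ["X"]
        assert any("only one comparison" in r.message for r in caplog.records)

    def test_absolute_mode_selects_negative_side_too(self):
        ca = pd.DataFrame({"pathway": ["X"], "nes": [1.0], "fdr": [0.01]})
        da = pd.DataFrame({"pathway": ["X"], "nes": [1.6], "fdr": [0.2]})
        assert not im.delta_nes_select(ca, da)["selected"].iloc[0]
        assert im.delta_nes_select(ca, da, absolute=True)["selected"].iloc[0]
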