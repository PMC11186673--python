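"""Interpretation layer: importance ranking, Shapley estimator, strand-aware
promoter mapping boundaries, differential methylation with BH, Fisher
over-representation against the hypergeometric closed form, and the
gene-subset property battery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import methylcascade as mc
from methylcascade.annotation import GenomicAnnotation
from methylcascade.cascade import MLP, DNNConfig, DNNStage, LabeledDataset
from methylcascade.interpret import (
    InterpretError, OverrepResult, _ranksum_p, shap_summary,
)

from conftest import planted_probes


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------

class TestRankImportances:
    def test_single_feature_cumulative_share_one(self):
        sel = mc.SelectedFeatures(pd.DataFrame(
            {"probe_id": ["cg1"], "importance": [0.4]}))
        ranked = mc.rank_importances(sel)
        assert ranked["cumulative_share"].iloc[-1] == pytest.approx(1.0)

    def test_ranking_is_permutation_of_selection(self, small_cascade):
        ranked = mc.rank_importances(small_cascade.selected)
        assert set(ranked["probe_id"]) == set(small_cascade.selected.probe_ids)
        assert ranked["cumulative_share"].iloc[-1] == pytest.approx(1.0)

    def test_planted_probes_rank_above_noise(self, small_cohort, small_cascade):
        ranked = mc.rank_importances(small_cascade.selected)
        planted = planted_probes(small_cohort)
        ranks = ranked.set_index("probe_id")["rank"]
        planted_ranks = [r for p, r in ranks.items() if p in planted]
        noise_ranks = [r for p, r in ranks.items() if p not in planted]
        assert np.median(planted_ranks) < np.median(noise_ranks)


# ---------------------------------------------------------------------------
# Shapley
# ---------------------------------------------------------------------------

def _manual_dnn(weights_zeroed_feature=None, seed=0):
    """2-feature, 2-class network where feature 0 is predictive."""
    rng = np.random.default_rng(seed)
    net = MLP(2, (8,), 2, "relu", rng)
    if weights_zeroed_feature is not None:
        net.W[0][weights_zeroed_feature, :] = 0.0
    return net


def _toy_model_and_dataset(zero_feature=None, n=60, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array(["a", "b"] * (n // 2))
    X = rng.normal(size=(2, n))
    X[0, y == "b"] += 4.0   # feature cg000 carries the signal
    m = pd.DataFrame(X, index=["cg000", "cg001"],
                     columns=[f"s{j}" for j in range(n)])
    ds = mc.split_train_test(LabeledDataset(m, pd.Series(y, index=m.columns)),
                             0.25, seed)
    stage = mc.train_dnn(ds, DNNConfig(hidden_layers=(8,), max_epochs=60,
                                       dropout=0.0, learning_rate=1e-2, seed=seed))
    if zero_feature is not None:
        stage.net.W[0][zero_feature, :] = 0.0
    sel = mc.SelectedFeatures(pd.DataFrame(
        {"probe_id": ["cg000", "cg001"], "importance": [0.9, 0.1]}))
    boost = mc.train_boost(ds, mc.BoostConfig(10, 2, seed=seed))
    model = mc.CascadeModel(boost_stage=boost, selected=sel, dnn_stage=stage,
                            class_names=stage.classes)
    return model, ds


class TestShapSummary:
    def test_severed_feature_gets_exactly_zero(self):
        model, ds = _toy_model_and_dataset(zero_feature=1)
        summary = shap_summary(model, ds, seed=1, n_permutations=8)
        assert summary.overall["cg001"] == 0.0
        assert summary.overall["cg000"] > 0.0

    def test_predictive_feature_dominates(self):
        model, ds = _toy_model_and_dataset()
        summary = shap_summary(model, ds, seed=2, n_permutations=10)
        assert summary.overall["cg000"] > summary.overall["cg001"]

    def test_same_seed_same_draws(self):
        model, ds = _toy_model_and_dataset()
        a = shap_summary(model, ds, seed=3, n_permutations=4)
        b = shap_summary(model, ds, seed=3, n_permutations=4)
        assert a.background_ids == b.background_ids
        assert a.explained_ids == b.explained_ids
        pd.testing.assert_frame_equal(a.per_class, b.per_class)

    def test_minimum_one_per_class_stratification(self):
        model, ds = _toy_model_and_dataset(n=12)  # 10% of 6/class rounds to 1
        summary = shap_summary(model, ds, seed=4, n_permutations=2)
        bg_labels = ds.labels.loc[summary.background_ids]
        assert set(bg_labels) == {"a", "b"}


# ---------------------------------------------------------------------------
# probe -> gene mapping
# ---------------------------------------------------------------------------

def _annotation(genes, probes):
    return GenomicAnnotation(
        probes=pd.DataFrame(probes, columns=["probe_id", "chrom", "pos"]),
        genes=pd.DataFrame(genes,
                           columns=["gene_id", "chrom", "start", "end",
                                    "strand", "biotype", "name"]))


@pytest.fixture()
def forward_gene():
    return _annotation(
        genes=[("G1", "chr1", 10_000, 12_000, "+", "protein_coding", "G1")],
        probes=[("p_body", "chr1", 11_000),
                ("p_prom_1000", "chr1", 9_000),
                ("p_prom_1500", "chr1", 8_500),
                ("p_out_1501", "chr1", 8_499),
                ("p_tss", "chr1", 10_000)])


class TestProbeGeneMapping:

    def test_forward_strand_windows(self, forward_gene):
        out = mc.map_probes_to_genes(
            ["p_body", "p_prom_1000", "p_prom_1500", "p_out_1501", "p_tss"],
            forward_gene)
        reasons = out.table.set_index("probe_id")["reason"]
        assert reasons["p_body"] == "body"
        assert reasons["p_prom_1000"] == "promoter"
        assert reasons["p_prom_1500"] == "promoter"   # exactly 1500 bp upstream
        assert "p_out_1501" in out.unmapped           # 1501 bp: outside
        assert reasons["p_tss"] == "body"             # TSS base belongs to body

    def test_reverse_strand_symmetry(self):
        ann = _annotation(
            genes=[("G2", "chr1", 10_000, 12_000, "-", "lncRNA", "G2")],
            probes=[("p_prom", "chr1", 12_500),
                    ("p_prom_edge", "chr1", 13_499),
                    ("p_out", "chr1", 13_500)])
        out = mc.map_probes_to_genes(["p_prom", "p_prom_edge", "p_out"], ann)
        reasons = out.table.set_index("probe_id")["reason"]
        assert reasons["p_prom"] == "promoter"
        assert reasons["p_prom_edge"] == "promoter"
        assert "p_out" in out.unmapped

    def test_body_takes_precedence_and_multi_gene_allowed(self):
        ann = _annotation(
            genes=[("A", "chr1", 10_000, 12_000, "+", "protein_coding", "A"),
                   ("B", "chr1", 11_000, 14_000, "+", "protein_coding", "B")],
            probes=[("p", "chr1", 11_500)])
        out = mc.map_probes_to_genes(["p"], ann)
        assert set(out.table["gene_id"]) == {"A", "B"}
        assert (out.table["reason"] == "body").all()

    def test_promoter_never_reported_inside_own_body(self):
        # probe inside the body that is also < 1500 bp from a - strand TSS
        ann = _annotation(
            genes=[("G", "chr1", 10_000, 12_000, "-", "protein_coding", "G")],
            probes=[("p", "chr1", 11_500)])
        out = mc.map_probes_to_genes(["p"], ann)
        assert out.table.iloc[0]["reason"] == "body"

    def test_exclusions_applied_after_mapping(self):
        ann = _annotation(
            genes=[("A", "chr1", 10_000, 12_000, "+", "protein_coding", "A"),
                   ("B", "chr1", 11_000, 14_000, "+", "protein_coding", "B")],
            probes=[("p", "chr1", 11_500)])
        out = mc.map_probes_to_genes(["p"], ann, exclusions=[("p", "B")])
        assert list(out.table["gene_id"]) == ["A"]

    def test_unknown_chromosome_warns_and_unmaps(self):
        ann = _annotation(
            genes=[("G", "chr1", 0, 100, "+", "protein_coding", "G")],
            probes=[("p", "chr9", 50)])
        with pytest.warns(UserWarning, match="chromosome"):
            out = mc.map_probes_to_genes(["p"], ann)
        assert out.unmapped == ["p"]

    def test_mapping_recovers_simulated_truth(self):
        config = mc.SimConfig(n_probes=150, seed=21)
        annotation, truth = mc.simulate_annotation(config)
        out = mc.map_probes_to_genes(list(annotation.probes["probe_id"]),
                                     annotation)
        got = out.table.set_index("probe_id")
        for row in truth.itertuples(index=False):
            if row.reason == "none":
                continue
            assert row.gene_id in out.genes_for(row.probe_id)
            sub = got.loc[[row.probe_id]]
            assert (sub.loc[sub["gene_id"] == row.gene_id, "reason"]
                    == row.reason).all()


# ---------------------------------------------------------------------------
# differential methylation
# ---------------------------------------------------------------------------

def bh_step_up_oracle(pvals):
    """Hand-rolled Benjamini-Hochberg step-up adjustment."""
    m = len(pvals)
    order = np.argsort(pvals)
    adjusted = np.empty(m)
    prev = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        value = min(prev, pvals[idx] * m / rank)
        adjusted[idx] = value
        prev = value
    return adjusted


class TestDifferentialMethylation:
    def test_identical_groups_yield_nothing(self, rng):
        m = pd.DataFrame(rng.normal(size=(50, 40)),
                         index=[f"cg{i}" for i in range(50)],
                         columns=[f"s{j}" for j in range(40)])
        condition = pd.Series(["cancer"] * 20 + ["normal"] * 20, index=m.columns)
        result = mc.differential_methylation(m, condition)
        assert result.significant_probes == []

    def test_constant_probe_gets_p_one(self, rng):
        m = pd.DataFrame(rng.normal(size=(3, 20)),
                         index=["cg0", "cg1", "cg2"],
                         columns=[f"s{j}" for j in range(20)])
        m.loc["cg1"] = 5.0
        condition = pd.Series(["cancer"] * 10 + ["normal"] * 10, index=m.columns)
        result = mc.differential_methylation(m, condition)
        assert result.table.loc["cg1", "p_value"] == 1.0

    def test_bh_matches_hand_rolled_step_up(self, rng):
        pvals = rng.uniform(size=20)
        from statsmodels.stats.multitest import multipletests
        adj = multipletests(pvals, method="fdr_bh")[1]
        np.testing.assert_allclose(adj, bh_step_up_oracle(pvals), atol=1e-12)

    def test_bh_monotone_in_raw_p_rank(self, rng):
        pvals = rng.uniform(size=50)
        from statsmodels.stats.multitest import multipletests
        adj = multipletests(pvals, method="fdr_bh")[1]
        order = np.argsort(pvals)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_mean_diff_is_case_minus_control(self):
        m = pd.DataFrame([[1.0] * 5 + [0.0] * 5], index=["cg0"],
                         columns=[f"s{j}" for j in range(10)])
        condition = pd.Series(["cancer"] * 5 + ["normal"] * 5, index=m.columns)
        result = mc.differential_methylation(m, condition)
        assert result.table.loc["cg0", "mean_diff"] == pytest.approx(1.0)

    def test_small_groups_rejected(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0]], index=["cg0"],
                         columns=["s0", "s1", "s2"])
        condition = pd.Series(["cancer", "normal", "normal"], index=m.columns)
        with pytest.raises(InterpretError):
            mc.differential_methylation(m, condition)

    def test_exact_path_matches_scipy_exact(self, rng):
        x = rng.normal(size=8)
        y = rng.normal(size=9) + 1
        _, p = _ranksum_p(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert p == pytest.approx(float(ref.pvalue))


# ---------------------------------------------------------------------------
# over-representation
# ---------------------------------------------------------------------------

def fisher_tail_oracle(overlap, n_query, n_set, n_background):
    """Exhaustive hypergeometric upper-tail sum."""
    from math import comb
    total = comb(n_background, n_query)
    acc = 0
    for k in range(overlap, min(n_query, n_set) + 1):
        acc += comb(n_set, k) * comb(n_background - n_set, n_query - k)
    return acc / total


class TestOverrepresentation:
    def test_query_equals_set_equals_background(self):
        genes = {f"g{i}" for i in range(10)}
        res = mc.overrepresentation(genes, genes, genes)
        assert res.p_value == pytest.approx(1.0)
        assert res.fraction_of_set == 1.0

    def test_zero_overlap_is_depleted_not_enriched(self):
        background = {f"g{i}" for i in range(100)}
        query = {f"g{i}" for i in range(50)}
        gene_set = {f"g{i}" for i in range(50, 100)}
        res = mc.overrepresentation(query, gene_set, background)
        assert res.p_value > 0.999

    def test_reference_table_matches_enumeration(self):
        # overlap=8, query-only=2, set-only=2, neither=88
        background = {f"g{i}" for i in range(100)}
        query = {f"g{i}" for i in range(10)}
        gene_set = {f"g{i}" for i in range(8)} | {"g90", "g91"}
        res = mc.overrepresentation(query, gene_set, background)
        assert res.overlap == 8
        assert res.p_value == pytest.approx(fisher_tail_oracle(8, 10, 10, 100),
                                            rel=1e-12)

    def test_matches_closed_form_across_small_tables(self, rng):
        for _ in range(300):
            n_bg = int(rng.integers(4, 201))
            n_q = int(rng.integers(1, n_bg + 1))
            n_s = int(rng.integers(1, n_bg + 1))
            ids = [f"g{i}" for i in range(n_bg)]
            background = set(ids)
            query = set(rng.choice(ids, n_q, replace=False))
            gene_set = set(rng.choice(ids, n_s, replace=False))
            res = mc.overrepresentation(query, gene_set, background)
            k = len(query & gene_set)
            assert res.p_value == pytest.approx(
                fisher_tail_oracle(k, n_q, n_s, n_bg), rel=1e-9)

    def test_empty_background_rejected(self):
        with pytest.raises(InterpretError):
            mc.overrepresentation({"a"}, {"a"}, set())


# ---------------------------------------------------------------------------
# subset property battery
# ---------------------------------------------------------------------------

def _battery_annotation(n=100, subset_near_snp=False):
    genes = []
    for i in range(n):
        start = 10_000 + i * 100_000
        genes.append((f"g{i}", "chr1", start, start + 5_000, "+", "lncRNA",
                      f"g{i}"))
    ann = GenomicAnnotation(
        probes=pd.DataFrame(columns=["probe_id", "chrom", "pos"]),
        genes=pd.DataFrame(genes, columns=["gene_id", "chrom", "start", "end",
                                           "strand", "biotype", "name"]))
    return ann


class TestSubsetPropertyBattery:
    def test_doubled_lengths_detected(self, rng):
        background = {f"g{i}" for i in range(100)}
        subset = {f"g{i}" for i in range(30)}
        lengths = pd.Series(
            {f"g{i}": (2.0 if i < 30 else 1.0) * rng.lognormal(8, 0.3)
             for i in range(100)})
        out = mc.subset_property_battery(subset, background,
                                         gene_lengths=lengths)
        row = out[out["test"] == "log_gene_length"].iloc[0]
        assert row["p_value"] < 0.001
        assert row["effect"] > 0

    def test_snp_proximity_fisher(self, rng):
        ann = _battery_annotation()
        background = {f"g{i}" for i in range(100)}
        subset = {f"g{i}" for i in range(20)}
        # subset genes get a SNP 500 bp upstream; everything else is ~50 kb away
        snps = [10_000 + i * 100_000 - 500 for i in range(20)]
        snps += [10_000 + i * 100_000 + 55_000 for i in range(20, 100)]
        out = mc.subset_property_battery(
            subset, background, annotation=ann,
            reference_snps={"chr1": np.array(snps, dtype=float)},
            distance_thresholds=[1_000])
        row = out[out["test"] == "snp_within_1000bp"].iloc[0]
        assert row["p_value"] < 0.01

    def test_null_subset_rarely_significant(self):
        n_sig = 0
        for sim in range(50):
            rng = np.random.default_rng(900 + sim)
            background = {f"g{i}" for i in range(80)}
            subset = set(rng.choice(sorted(background), 25, replace=False))
            lengths = pd.Series({g: rng.lognormal(8, 0.5) for g in background})
            expression = pd.Series({g: rng.lognormal(3, 1.0) for g in background})
            out = mc.subset_property_battery(subset, background,
                                             gene_lengths=lengths,
                                             expression=expression)
            n_sig += (out["p_value"] < 0.05).any()
        assert n_sig <= 10  # >= 90% of null simulations fully non-significant

    def test_missing_table_names_test(self):
        with pytest.raises(InterpretError, match="nothing to test"):
            mc.subset_property_battery({"g1"}, {"g1", "g2"})
        with pytest.raises(InterpretError, match="snp_proximity"):
            mc.subset_property_battery({"g1"}, {"g1", "g2"},
                                       reference_snps={"chr1": np.array([1.0])})

    def test_subset_must_be_in_background(self):
        with pytest.raises(InterpretError):
            mc.subset_property_battery({"zz"}, {"g1"})
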