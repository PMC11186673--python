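"""Feature interpretability downstream of the cascade.

Covers: gain-importance ranking with cumulative shares, Shapley-value
summaries of the network (permutation-sampling estimator against a stratified
background set), strand-aware probe-to-gene mapping (gene body or the 1500-bp
promoter window upstream of the TSS), two-group differential methylation on
M-values (Wilcoxon rank-sum + Benjamini-Hochberg, dual significance
criterion), Fisher over-representation against gene sets, and the
gene-subset property battery (overlap / SNP-proximity / length / expression
tests) generalizable to any gene subset such as lncRNAs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import GenomicAnnotation, normalize_chrom
from .cascade import CascadeModel, LabeledDataset, SelectedFeatures

DEFAULT_PROMOTER_BP = 1500
DEFAULT_DM_ALPHA = 0.01
DEFAULT_DM_MIN_ABS_DIFF = 2.0


class InterpretError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Importance ranking
# ---------------------------------------------------------------------------

def rank_importances(selected: SelectedFeatures, top_k: int | None = None) -> pd.DataFrame:
    """Descending gain order (ties broken by probe ID) with each feature's
    cumulative share of total importance."""
    table = selected.table.copy()
    total = table["importance"].sum()
    table["cumulative_share"] = table["importance"].cumsum() / total
    table["rank"] = np.arange(1, len(table) + 1)
    if top_k is not None:
        table = table.head(top_k)
    return table.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Shapley values
# ---------------------------------------------------------------------------

@dataclass
class ShapSummary:
    per_class: pd.DataFrame        # features x classes, mean |shap|
    overall: pd.Series             # mean over classes
    background_ids: list[str]
    explained_ids: list[str]
    notes: dict = field(default_factory=dict)


def _stratified_sample(ids: np.ndarray, labels: np.ndarray, fraction: float,
                       rng: np.random.Generator) -> list[str]:
    """At least one sample per class even when 10% of a class rounds to 0."""
    chosen = []
    for cls in np.unique(labels):
        members = ids[labels == cls]
        n = max(1, int(round(fraction * len(members))))
        chosen.extend(rng.choice(members, size=n, replace=False))
    return sorted(chosen)


def shap_summary(model: CascadeModel, dataset: LabeledDataset, seed: int = 0,
                 background_fraction: float = 0.10,
                 explain_fraction: float = 0.10,
                 n_permutations: int = 20) -> ShapSummary:
    """Per-feature mean absolute Shapley value of the network's class
    probabilities.

    Background set: stratified ``background_fraction`` of the training split.
    Explanation set: stratified ``explain_fraction`` of all samples.  Shapley
    values are estimated by permutation sampling: for each sampled feature
    ordering and background row, features are switched one at a time from the
    background value to the explained sample's value and the change in output
    is credited to the switched feature.  A feature the network ignores gets
    exactly zero.
    """
    rng = np.random.default_rng(int(seed) % 2**31)
    stage = model.dnn_stage
    features = model.selected.probe_ids
    m = dataset.m_values.loc[features]

    all_ids = np.array(m.columns)
    labels = dataset.labels.loc[all_ids].to_numpy()
    train_mask = (dataset.split.loc[all_ids] == "train").to_numpy()
    background_ids = _stratified_sample(all_ids[train_mask], labels[train_mask],
                                        background_fraction, rng)
    explained_ids = _stratified_sample(all_ids, labels, explain_fraction, rng)

    B = m[background_ids].to_numpy(dtype=float).T       # n_bg x d
    E = m[explained_ids].to_numpy(dtype=float).T        # n_ex x d
    n_classes = len(stage.classes)
    d = len(features)

    abs_sum = np.zeros((d, n_classes))
    for x in E:
        phi = np.zeros((d, n_classes))
        for _ in range(n_permutations):
            order = rng.permutation(d)
            b = B[rng.integers(len(B))]
            # build the d+1 hybrid rows for this ordering in one batch
            hybrids = np.tile(b, (d + 1, 1))
            for step, j in enumerate(order):
                hybrids[step + 1:, j] = x[j]
            out = stage.predict_proba(hybrids)
            phi[order] += out[1:] - out[:-1]
        phi /= n_permutations
        abs_sum += np.abs(phi)
    per_class = pd.DataFrame(abs_sum / len(E), index=features,
                             columns=stage.classes)
    overall = per_class.mean(axis=1)
    return ShapSummary(per_class=per_class, overall=overall,
                       background_ids=list(background_ids),
                       explained_ids=list(explained_ids),
                       notes={"n_permutations": n_permutations})


# ---------------------------------------------------------------------------
# Probe -> gene mapping
# ---------------------------------------------------------------------------

@dataclass
class ProbeGeneMap:
    """Long-format probe->gene links with the mapping reason."""

    table: pd.DataFrame  # columns: probe_id, gene_id, reason (body|promoter)
    unmapped: list[str] = field(default_factory=list)

    def genes_for(self, probe_id: str) -> list[str]:
        t = self.table
        return sorted(t.loc[t["probe_id"] == probe_id, "gene_id"].unique())

    def gene_list(self) -> list[str]:
        return sorted(self.table["gene_id"].unique())


def map_probes_to_genes(
    probes: list[str],
    annotation: GenomicAnnotation,
    promoter_bp: int = DEFAULT_PROMOTER_BP,
    exclusions: list[tuple[str, str]] | None = None,
) -> ProbeGeneMap:
    """Map each probe to every gene whose body it overlaps or whose
    strand-aware promoter window it falls in.

    Body: position in [start, end).  Promoter (+): [TSS - promoter_bp, TSS);
    promoter (-): positions [end, end + promoter_bp), i.e. the ``promoter_bp``
    bases immediately upstream of the TSS at ``end - 1``, excluding the TSS
    base itself.  A probe inside the body is reported as body even if it also
    lies in another window of the same gene.  ``exclusions`` (probe_id,
    gene_id) pairs are removed after mapping — the file-driven counterpart of
    manual curation of multi-gene probes.
    """
    import warnings

    probe_tab = annotation.probes.set_index("probe_id")
    genes = annotation.genes
    rows, unmapped = [], []
    by_chrom = {c: g for c, g in genes.groupby(genes["chrom"].map(normalize_chrom))}
    for pid in probes:
        if pid not in probe_tab.index:
            warnings.warn(f"probe {pid} missing from annotation; left unmapped")
            unmapped.append(pid)
            continue
        chrom = normalize_chrom(probe_tab.at[pid, "chrom"])
        pos = int(probe_tab.at[pid, "pos"])
        g = by_chrom.get(chrom)
        if g is None:
            warnings.warn(f"probe {pid} on unannotated chromosome {chrom!r}")
            unmapped.append(pid)
            continue
        start = g["start"].to_numpy()
        end = g["end"].to_numpy()
        plus = g["strand"].to_numpy() == "+"
        body = (start <= pos) & (pos < end)
        prom_plus = plus & (start - promoter_bp <= pos) & (pos < start)
        prom_minus = ~plus & (end <= pos) & (pos < end + promoter_bp)
        promoter = (prom_plus | prom_minus) & ~body
        hit = body | promoter
        if not hit.any():
            unmapped.append(pid)
            continue
        for gid, is_body in zip(g.loc[hit, "gene_id"], body[hit]):
            rows.append((pid, gid, "body" if is_body else "promoter"))
    table = pd.DataFrame(rows, columns=["probe_id", "gene_id", "reason"])
    if exclusions:
        excl = set(map(tuple, exclusions))
        keep = [tuple(r) not in excl
                for r in table[["probe_id", "gene_id"]].itertuples(index=False)]
        table = table[keep].reset_index(drop=True)
    return ProbeGeneMap(table=table, unmapped=unmapped)


# ---------------------------------------------------------------------------
# Differential methylation
# ---------------------------------------------------------------------------

@dataclass
class DmResult:
    table: pd.DataFrame  # statistic, p_value, p_adjusted, mean_diff, significant
    alpha: float
    min_abs_diff: float

    @property
    def significant_probes(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


def _ranksum_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sample Wilcoxon rank-sum p; exact for small tie-free groups,
    tie-corrected normal approximation otherwise.  Constant pooled input
    gives p = 1 by convention."""
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    if max(len(x), len(y)) <= 25 and len(np.unique(pooled)) == len(pooled):
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def differential_methylation(
    m_values: pd.DataFrame,
    condition: pd.Series,
    case: str = "cancer",
    control: str = "normal",
    alpha: float = DEFAULT_DM_ALPHA,
    min_abs_diff: float = DEFAULT_DM_MIN_ABS_DIFF,
) -> DmResult:
    """Per-probe Wilcoxon rank-sum on M-values (case vs control), BH
    adjustment over all tested probes; a probe is significant when its
    adjusted p < ``alpha`` AND |mean difference| (case - control) >
    ``min_abs_diff``."""
    condition = condition.loc[m_values.columns]
    case_ids = condition.index[condition == case]
    ctrl_ids = condition.index[condition == control]
    if len(case_ids) < 2 or len(ctrl_ids) < 2:
        raise InterpretError("need at least 2 samples per condition")
    X = m_values[case_ids].to_numpy(dtype=float)
    Y = m_values[ctrl_ids].to_numpy(dtype=float)
    stats_p = [_ranksum_p(X[i], Y[i]) for i in range(X.shape[0])]
    statistic = np.array([s for s, _ in stats_p])
    p_raw = np.array([p for _, p in stats_p])
    p_adj = multipletests(p_raw, method="fdr_bh")[1]
    mean_diff = X.mean(axis=1) - Y.mean(axis=1)
    table = pd.DataFrame({
        "statistic": statistic,
        "p_value": p_raw,
        "p_adjusted": p_adj,
        "mean_diff": mean_diff,
        "significant": (p_adj < alpha) & (np.abs(mean_diff) > min_abs_diff),
    }, index=m_values.index)
    return DmResult(table=table, alpha=alpha, min_abs_diff=min_abs_diff)


# ---------------------------------------------------------------------------
# Over-representation
# ---------------------------------------------------------------------------

@dataclass
class OverrepResult:
    overlap: int
    n_query: int
    n_set: int
    n_background: int
    fraction_of_set: float
    odds_ratio: float
    p_value: float
    sidedness: str = "greater"


def overrepresentation(query: set[str], gene_set: set[str],
                       background: set[str]) -> OverrepResult:
    """One-sided (enrichment) Fisher exact test of query-vs-set overlap.

    Both query and set are intersected with the background first; p is the
    hypergeometric upper tail P(X >= overlap)."""
    background = set(background)
    if not background:
        raise InterpretError("empty background gene set")
    query = set(query) & background
    if not set(query) <= background:
        raise InterpretError("query genes must be drawn from the background")
    gene_set = set(gene_set) & background
    overlap = len(query & gene_set)
    n_bg, n_q, n_s = len(background), len(query), len(gene_set)
    p = float(stats.hypergeom.sf(overlap - 1, n_bg, n_s, n_q))
    a = overlap
    b = n_q - overlap
    c = n_s - overlap
    d = n_bg - n_q - n_s + overlap
    odds = np.inf if b * c == 0 and a * d > 0 else (
        (a * d) / (b * c) if b * c else np.nan)
    return OverrepResult(overlap=overlap, n_query=n_q, n_set=n_s,
                         n_background=n_bg,
                         fraction_of_set=(overlap / n_s if n_s else np.nan),
                         odds_ratio=float(odds), p_value=p)


# ---------------------------------------------------------------------------
# Gene-subset property battery
# ---------------------------------------------------------------------------

def _fisher_two_sided(in_subset: np.ndarray, flag: np.ndarray) -> tuple[float, float]:
    table = [[int((in_subset & flag).sum()), int((in_subset & ~flag).sum())],
             [int((~in_subset & flag).sum()), int((~in_subset & ~flag).sum())]]
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def _nearest_distance(points: np.ndarray, starts: np.ndarray,
                      ends: np.ndarray) -> np.ndarray:
    """Distance from each [start, end) interval to its nearest point
    (0 if a point falls inside)."""
    points = np.sort(points)
    out = np.empty(len(starts))
    for i, (s, e) in enumerate(zip(starts, ends)):
        idx = np.searchsorted(points, s)
        best = np.inf
        for j in (idx - 1, idx, np.searchsorted(points, e)):
            if 0 <= j < len(points):
                p = points[j]
                if s <= p < e:
                    best = 0.0
                    break
                best = min(best, abs(p - s), abs(p - (e - 1)))
        out[i] = best
    return out


def subset_property_battery(
    subset: set[str],
    background: set[str],
    annotation: GenomicAnnotation | None = None,
    gene_lengths: pd.Series | None = None,
    exon_lengths: pd.Series | None = None,
    expression: pd.Series | None = None,
    reference_genes: set[str] | None = None,
    reference_snps: dict[str, np.ndarray] | None = None,
    distance_thresholds: list[int] = (1_000, 10_000, 100_000),
    reference_gene_distance_bp: int = 1_000,
) -> pd.DataFrame:
    """Test whether a gene subset (e.g. the model's lncRNAs) differs from the
    rest of the background in reference-list overlap, SNP proximity,
    proximity to reference genes, log gene/exon length (longest transcript)
    and log expression.  Fisher tests are two-sided; Wilcoxon rank-sum on the
    logged values.  Returns one row per executed test with p-values and
    effect summaries; a missing input table raises naming the skipped test.
    """
    subset = set(subset)
    background = set(background)
    if not subset <= background:
        raise InterpretError("subset genes must be drawn from the background")
    order = sorted(background)
    in_subset = np.array([g in subset for g in order])
    rows = []

    def _wilcoxon_row(name, values: pd.Series):
        if values is None:
            raise InterpretError(f"missing table for test {name!r}; test skipped")
        v = values.reindex(order).to_numpy(dtype=float)
        ok = np.isfinite(v) & (v > 0)
        logs = np.log(v[ok])
        grp = in_subset[ok]
        stat, p = _ranksum_p(logs[grp], logs[~grp])
        rows.append({"test": name, "statistic": stat, "p_value": p,
                     "effect": float(np.median(logs[grp]) - np.median(logs[~grp])),
                     "sidedness": "two-sided", "kind": "wilcoxon-log"})

    if reference_genes is not None:
        flag = np.array([g in reference_genes for g in order])
        odds, p = _fisher_two_sided(in_subset, flag)
        rows.append({"test": "reference_list_overlap", "statistic": odds,
                     "p_value": p,
                     "effect": int((in_subset & flag).sum()),
                     "sidedness": "two-sided", "kind": "fisher"})

    if reference_snps is not None:
        if annotation is None:
            raise InterpretError(
                "missing annotation for test 'snp_proximity'; test skipped")
        genes = annotation.genes.set_index("gene_id").reindex(order)
        dist = np.full(len(order), np.inf)
        for chrom, points in reference_snps.items():
            mask = genes["chrom"].map(
                lambda c: normalize_chrom(str(c))) == normalize_chrom(chrom)
            mask &= genes["start"].notna()
            if mask.any():
                dist[mask.to_numpy()] = _nearest_distance(
                    np.asarray(points, dtype=float),
                    genes.loc[mask, "start"].to_numpy(dtype=float),
                    genes.loc[mask, "end"].to_numpy(dtype=float))
        for threshold in distance_thresholds:
            flag = dist <= threshold
            odds, p = _fisher_two_sided(in_subset, flag)
            rows.append({"test": f"snp_within_{threshold}bp", "statistic": odds,
                         "p_value": p, "effect": int((in_subset & flag).sum()),
                         "sidedness": "two-sided", "kind": "fisher"})

    if reference_genes is not None and annotation is not None:
        ref = annotation.genes[annotation.genes["gene_id"].isin(reference_genes)]
        genes = annotation.genes.set_index("gene_id").reindex(order)
        dist = np.full(len(order), np.inf)
        for chrom, g in ref.groupby(ref["chrom"].map(normalize_chrom)):
            # nearest reference-gene edge, per chromosome
            pts = np.sort(np.concatenate([g["start"].to_numpy(dtype=float),
                                          g["end"].to_numpy(dtype=float) - 1]))
            mask = genes["chrom"].map(
                lambda c: normalize_chrom(str(c))) == chrom
            mask &= genes["start"].notna()
            if mask.any():
                dist[mask.to_numpy()] = _nearest_distance(
                    pts, genes.loc[mask, "start"].to_numpy(dtype=float),
                    genes.loc[mask, "end"].to_numpy(dtype=float))
        is_ref = np.array([g in reference_genes for g in order])
        flag = (dist <= reference_gene_distance_bp) & ~is_ref
        odds, p = _fisher_two_sided(in_subset[~is_ref], flag[~is_ref])
        rows.append({"test": f"reference_gene_within_{reference_gene_distance_bp}bp",
                     "statistic": odds, "p_value": p,
                     "effect": int((in_subset & flag).sum()),
                     "sidedness": "two-sided", "kind": "fisher"})

    if gene_lengths is not None:
        _wilcoxon_row("log_gene_length", gene_lengths)
    if exon_lengths is not None:
        _wilcoxon_row("log_exon_length_longest_transcript", exon_lengths)
    if expression is not None:
        _wilcoxon_row("log_expression", expression)

    if not rows:
        raise InterpretError("no feature tables supplied; nothing to test")
    return pd.DataFrame(rows)
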