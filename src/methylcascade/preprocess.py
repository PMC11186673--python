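"""Methylation-array preprocessing.

Beta values (methylated signal fraction, in [0,1]) arrive as a probe-by-sample
matrix.  The pipeline filters noisy/unplaced/over-missing probes, imputes the
remaining missing entries with a k-nearest-neighbour scheme over probe rows,
and converts to M-values, the logit2 transform

    M = log2(beta / (1 - beta)),

which is more homoscedastic and is the scale used by every downstream stage.

All matrices are pandas DataFrames with probes as the row index and samples as
columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import GenomicAnnotation, is_canonical_chrom

DEFAULT_MAX_MISSING_FRACTION = 0.05
DEFAULT_KNN_K = 10
DEFAULT_KNN_ROWMAX = 0.25
DEFAULT_EPSILON = 1e-6
DEFAULT_NA_BETA = 0.5


class PreprocessError(ValueError):
    pass


@dataclass
class FilterReport:
    """Per-rule accounting of probe removal.

    A probe is counted under the first rule that removes it; rule order is
    blacklist -> chromosome -> missingness, so the counts always reconcile:
    ``n_input_probes == n_retained + sum(removals)``.
    """

    n_input_probes: int
    n_removed_blacklist: int
    n_removed_chromosome: int
    n_removed_missingness: int
    n_retained: int
    removed_ids: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = (self.n_removed_blacklist + self.n_removed_chromosome
                 + self.n_removed_missingness + self.n_retained)
        if total != self.n_input_probes:
            raise PreprocessError(
                f"filter report does not reconcile: {self.n_input_probes} input != "
                f"{self.n_retained} retained + removals")

    def to_dict(self) -> dict:
        return {
            "n_input_probes": self.n_input_probes,
            "n_removed_blacklist": self.n_removed_blacklist,
            "n_removed_chromosome": self.n_removed_chromosome,
            "n_removed_missingness": self.n_removed_missingness,
            "n_retained": self.n_retained,
            "removed_ids": {k: list(v) for k, v in self.removed_ids.items()},
        }


def _validate_beta(beta: pd.DataFrame) -> None:
    if beta.index.has_duplicates:
        raise PreprocessError("duplicate probe IDs in beta matrix")
    if beta.columns.has_duplicates:
        raise PreprocessError("duplicate sample IDs in beta matrix")
    vals = beta.to_numpy(dtype=float)
    finite = vals[~np.isnan(vals)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise PreprocessError("beta values outside [0, 1]")


def filter_probes(
    beta: pd.DataFrame,
    blacklist: set[str] | None = None,
    probe_annotation: GenomicAnnotation | None = None,
    max_missing_fraction: float = DEFAULT_MAX_MISSING_FRACTION,
) -> tuple[pd.DataFrame, FilterReport]:
    """Remove blacklisted probes, probes not on chr1-22/X/Y, then probes with
    a missing fraction strictly greater than ``max_missing_fraction``.

    Probes absent from the annotation are treated as non-chromosomal.  If no
    annotation is given the chromosome rule is skipped.
    """
    _validate_beta(beta)
    blacklist = set(blacklist or ())
    probe_ids = beta.index.to_numpy()

    bl_mask = np.array([p in blacklist for p in probe_ids])

    if probe_annotation is not None:
        chrom = probe_annotation.probe_chromosomes()
        keep_chrom = {p for p, c in chrom.items() if is_canonical_chrom(c)}
        chrom_mask = np.array([p not in keep_chrom for p in probe_ids])
    else:
        chrom_mask = np.zeros(len(probe_ids), dtype=bool)
    chrom_mask &= ~bl_mask  # first-rule-wins accounting

    missing_frac = beta.isna().mean(axis=1).to_numpy()
    miss_mask = (missing_frac > max_missing_fraction) & ~bl_mask & ~chrom_mask

    retained = ~(bl_mask | chrom_mask | miss_mask)
    out = beta.loc[retained]
    if out.shape[0] == 0:
        raise PreprocessError("all probes removed by filtering")
    report = FilterReport(
        n_input_probes=len(probe_ids),
        n_removed_blacklist=int(bl_mask.sum()),
        n_removed_chromosome=int(chrom_mask.sum()),
        n_removed_missingness=int(miss_mask.sum()),
        n_retained=int(retained.sum()),
        removed_ids={
            "blacklist": list(probe_ids[bl_mask]),
            "chromosome": list(probe_ids[chrom_mask]),
            "missingness": list(probe_ids[miss_mask]),
        },
    )
    return out, report


def impute_knn(beta: pd.DataFrame, k: int = DEFAULT_KNN_K,
               rowmax: float = DEFAULT_KNN_ROWMAX) -> pd.DataFrame:
    """k-nearest-neighbour imputation over probe rows.

    Each missing entry of a probe row whose missing fraction is <= ``rowmax``
    is replaced by the mean of that sample's value over the ``k`` nearest
    probe rows, where distance is Euclidean over mutually observed samples
    (scaled to the full sample count) and neighbours must be observed in the
    target sample.  Probe rows with missing fraction > ``rowmax`` fall back to
    the per-sample column mean.  Mirrors the semantics of the R ``impute``
    package defaults (k=10, rowmax=0.25).
    """
    _validate_beta(beta)
    X = beta.to_numpy(dtype=float).copy()
    n_probes, n_samples = X.shape
    if n_probes < k + 1:
        raise PreprocessError(
            f"kNN imputation requires at least k+1={k + 1} probes, got {n_probes}")
    miss = np.isnan(X)
    if not miss.any():
        return beta.copy()

    col_means = np.nanmean(X, axis=0)
    row_miss_frac = miss.mean(axis=1)
    out = X.copy()

    fallback_rows = np.where((row_miss_frac > rowmax) & miss.any(axis=1))[0]
    for i in fallback_rows:
        out[i, miss[i]] = col_means[miss[i]]

    knn_rows = np.where((row_miss_frac <= rowmax) & miss.any(axis=1))[0]
    for i in knn_rows:
        obs_i = ~miss[i]
        # squared distance over mutually observed samples, scaled to full width
        shared = obs_i[None, :] & ~miss
        n_shared = shared.sum(axis=1)
        diff = np.where(shared, X[i] - np.where(miss, 0.0, X), 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            dist = np.sqrt(np.sum(diff ** 2, axis=1) / n_shared * n_samples)
        dist[n_shared == 0] = np.inf
        dist[i] = np.inf
        for j in np.where(miss[i])[0]:
            candidates = np.where(~miss[:, j] & np.isfinite(dist))[0]
            if len(candidates) < k:
                raise PreprocessError(
                    f"kNN imputation needs k={k} neighbour rows observed in "
                    f"sample {beta.columns[j]!r}; only {len(candidates)} available")
            order = candidates[np.lexsort((candidates, dist[candidates]))][:k]
            out[i, j] = X[order, j].mean()

    result = pd.DataFrame(out, index=beta.index, columns=beta.columns)
    return result.clip(0.0, 1.0)


def beta_to_m(beta: pd.DataFrame, epsilon: float = DEFAULT_EPSILON) -> pd.DataFrame:
    """Logit2 transform M = log2(beta/(1-beta)), clipping beta to
    [epsilon, 1-epsilon] first so the boundary values stay finite."""
    if beta.isna().to_numpy().any():
        raise PreprocessError(
            "beta matrix contains missing entries; impute before transforming")
    clipped = beta.clip(epsilon, 1.0 - epsilon)
    return np.log2(clipped / (1.0 - clipped))


def m_to_beta(m: pd.DataFrame) -> pd.DataFrame:
    """Inverse logit2: beta = 2^M / (1 + 2^M), computed stably via expit."""
    from scipy.special import expit
    vals = m.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise PreprocessError("M-value matrix contains non-finite entries")
    return pd.DataFrame(expit(vals * np.log(2.0)), index=m.index, columns=m.columns)


def intersect_features(matrices: list[pd.DataFrame]) -> list[pd.DataFrame]:
    """Restrict every matrix to the common probe set, in one canonical
    (sorted) probe order shared across outputs."""
    if not matrices:
        raise PreprocessError("need at least one matrix")
    common = set(matrices[0].index)
    for mat in matrices[1:]:
        common &= set(mat.index)
    if not common:
        raise PreprocessError("empty probe intersection across matrices")
    order = sorted(common)
    return [mat.loc[order] for mat in matrices]


def prepare_external(
    raw: pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame],
    reference_probes: list[str],
    na_beta: float = DEFAULT_NA_BETA,
    epsilon: float = DEFAULT_EPSILON,
) -> pd.DataFrame:
    """Align an external cohort to a trained model's feature list.

    ``raw`` is either a beta matrix or a ``(methylated, unmethylated)`` count
    pair (beta = meth / (meth + unmeth); zero total counts are missing).  The
    matrix is reindexed to ``reference_probes``; probes absent from the
    external data and any remaining missing entries are set to the constant
    ``na_beta`` (no cohort-level imputation, so single samples can be
    processed in isolation), then transformed to M-values.
    """
    if not len(reference_probes):
        raise PreprocessError("reference probe list is empty")
    if isinstance(raw, tuple):
        meth, unmeth = raw
        meth, unmeth = meth.align(unmeth, join="outer")
        total = meth + unmeth
        with np.errstate(invalid="ignore", divide="ignore"):
            beta = meth / total
        beta = beta.where(total > 0)  # zero totals -> missing
    else:
        beta = raw.copy()
        _validate_beta(beta)
    aligned = beta.reindex(index=list(reference_probes))
    aligned = aligned.fillna(na_beta)
    return beta_to_m(aligned, epsilon=epsilon)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_beta_tsv(path) -> pd.DataFrame:
    """Probe-by-sample matrix: first column = probe IDs, header = sample IDs."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_matrix_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="probe_id")


def read_blacklist(path) -> set[str]:
    """One probe ID per line; blank lines and '#' comments ignored."""
    with open(path) as fh:
        return {ln.strip() for ln in fh
                if ln.strip() and not ln.lstrip().startswith("#")}
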