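"""Two-phase survival screening on gene expression.

Phase 1 (differentiation): one Cox proportional-hazards fit per gene with
age, stage and gender covariates; genes with Wald p < 0.05 enter a joint Cox
model whose linear predictor ("hazard score") splits the cohort at its median
for Kaplan-Meier curves and a log-rank test.

Phase 2 (prediction): thirty stratified 75/25 train/test splits; inside each
training fold the screen is re-run (no leakage), three Cox models are fitted
(genes only, covariates only, genes + covariates) and each is scored by the
cumulative/dynamic time-dependent ROC AUC at a 5-year horizon with inverse-
probability-of-censoring weights.

Expression is rank-based inverse-normal transformed by default; pass
``normalize=False`` for variance-stabilized input produced upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_SELECTION_P = 0.05
DEFAULT_N_REPEATS = 30
DEFAULT_TRAIN_FRACTION = 0.75
DEFAULT_HORIZON_YEARS = 5.0
RIDGE_FALLBACK_PENALIZER = 0.1

_STAGE_MAP = {"I": 1, "II": 2, "III": 3, "IV": 4}


class SurvivalError(ValueError):
    pass


def rank_inverse_normal(values: pd.Series | np.ndarray, offset: float = 0.375) -> np.ndarray:
    """Blom rank-based inverse-normal transform."""
    v = np.asarray(values, dtype=float)
    ranks = stats.rankdata(v)
    return stats.norm.ppf((ranks - offset) / (len(v) - 2 * offset + 1))


def _encode_covariates(records: pd.DataFrame, use_gender: bool) -> pd.DataFrame:
    """age (numeric), stage (ordinal I-IV -> 1-4), gender (F=0/M=1).
    Samples with unknown stage are dropped with a log message."""
    cov = pd.DataFrame(index=records.index)
    cov["age"] = pd.to_numeric(records["age"], errors="coerce")
    stage = records["stage"]
    if stage.dtype == object:
        stage = stage.map(lambda s: _STAGE_MAP.get(str(s).strip().upper(), np.nan))
    cov["stage"] = pd.to_numeric(stage, errors="coerce")
    if use_gender and "gender" in records.columns:
        genders = records["gender"].dropna().unique()
        if len(genders) > 1:  # omit for single-gender cohorts
            cov["gender"] = (records["gender"] == "M").astype(float)
    complete = cov.notna().all(axis=1)
    if (~complete).any():
        logger.info("dropping %d samples with incomplete covariates",
                    int((~complete).sum()))
    return cov.loc[complete]


def _fit_cox(df: pd.DataFrame, penalizer: float = 0.0) -> CoxPHFitter:
    cph = CoxPHFitter(penalizer=penalizer)
    cph.fit(df, duration_col="time", event_col="event")
    return cph


def _fit_cox_ridge_fallback(df: pd.DataFrame) -> tuple[CoxPHFitter, bool]:
    """Plain fit first; on non-convergence (e.g. collinear genes) refit with a
    small ridge penalty so coefficients stay finite."""
    try:
        with np.errstate(all="ignore"):
            cph = _fit_cox(df)
        if np.isfinite(cph.params_).all():
            return cph, False
    except (ConvergenceError, ValueError, np.linalg.LinAlgError):
        pass
    return _fit_cox(df, penalizer=RIDGE_FALLBACK_PENALIZER), True


@dataclass
class ScreenResult:
    per_gene: pd.DataFrame          # coefficient, p_value per screened gene
    selected: list[str]             # Wald p < threshold
    selection_threshold: float
    joint_coefficients: pd.Series
    hazard_score: pd.Series         # per-sample joint linear predictor
    ridge_fallback: bool
    dropped_genes: list[str] = field(default_factory=list)
    notes: dict = field(default_factory=dict)


def screen_genes(
    records: pd.DataFrame,
    expression: pd.DataFrame,
    genes: list[str] | None = None,
    selection_p: float = DEFAULT_SELECTION_P,
    normalize: bool = True,
    joint_with_covariates: bool = True,
) -> ScreenResult:
    """Per-gene Cox screen with covariates, then a joint model over the
    selected genes.

    ``records`` needs time, event, age, stage (and optionally gender) indexed
    by sample; ``expression`` is genes x samples.  Non-converged single-gene
    fits are dropped with logging; the joint fit falls back to a small ridge
    penalty when unpenalized Newton iterations fail (collinear genes).
    """
    genes = list(genes) if genes is not None else list(expression.index)
    missing = [g for g in genes if g not in expression.index]
    if missing:
        raise SurvivalError(f"genes absent from expression matrix: {missing[:5]}")
    if int(records["event"].sum()) < 2:
        raise SurvivalError(
            "fewer than 2 events: not enough data for the Cox screen to converge")

    cov = _encode_covariates(records, use_gender=True)
    ids = cov.index
    base = pd.DataFrame({
        "time": records.loc[ids, "time"].astype(float),
        "event": records.loc[ids, "event"].astype(int),
    }).join(cov)

    expr = expression.loc[genes, ids].astype(float)
    if normalize:
        expr = pd.DataFrame(
            np.vstack([rank_inverse_normal(expr.loc[g]) for g in genes]),
            index=genes, columns=ids)

    rows, dropped = [], []
    for gene in genes:
        df = base.copy()
        df["gene"] = expr.loc[gene].to_numpy()
        try:
            with np.errstate(all="ignore"):
                cph = _fit_cox(df)
            rows.append({"gene": gene,
                         "coefficient": float(cph.params_["gene"]),
                         "p_value": float(cph.summary.loc["gene", "p"])})
        except (ConvergenceError, ValueError, np.linalg.LinAlgError) as err:
            logger.info("dropping gene %s: Cox fit failed (%s)", gene, err)
            dropped.append(gene)
    per_gene = pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame(
        columns=["coefficient", "p_value"])
    selected = list(per_gene.index[per_gene["p_value"] < selection_p])

    if selected:
        joint_df = base.copy() if joint_with_covariates else base[["time", "event"]].copy()
        for gene in selected:
            joint_df[gene] = expr.loc[gene].to_numpy()
        joint, ridge = _fit_cox_ridge_fallback(joint_df)
        joint_coefs = joint.params_
        hazard = pd.Series(
            joint_df.drop(columns=["time", "event"]).to_numpy()
            @ joint_coefs.to_numpy(), index=ids, name="hazard_score")
    else:
        joint_coefs = pd.Series(dtype=float)
        hazard = pd.Series(0.0, index=ids, name="hazard_score")
        ridge = False
    return ScreenResult(per_gene=per_gene, selected=selected,
                        selection_threshold=selection_p,
                        joint_coefficients=joint_coefs, hazard_score=hazard,
                        ridge_fallback=ridge, dropped_genes=dropped,
                        notes={"normalization": "rank-inverse-normal" if normalize
                               else "pre-normalized",
                               "joint_with_covariates": joint_with_covariates})


# ---------------------------------------------------------------------------
# Kaplan-Meier median split
# ---------------------------------------------------------------------------

@dataclass
class KmSplit:
    groups: pd.Series              # 'high' / 'low' per sample
    log_rank_p: float
    curves: pd.DataFrame           # timeline, survival per group (long format)
    median_hazard: float
    n_ties_at_median: int


def km_median_split(screen: ScreenResult, records: pd.DataFrame) -> KmSplit:
    """Split at the median joint-model hazard score (ties go to the low
    group), estimate a Kaplan-Meier curve per group and test with log-rank."""
    hazard = screen.hazard_score
    ids = hazard.index
    med = float(np.median(hazard))
    groups = pd.Series(np.where(hazard > med, "high", "low"), index=ids)
    n_ties = int((hazard == med).sum())
    t = records.loc[ids, "time"].astype(float)
    e = records.loc[ids, "event"].astype(int)
    if groups.nunique() < 2:
        raise SurvivalError("median split produced a single group "
                            f"({n_ties} scores tied at the median)")
    curves = []
    for name in ("low", "high"):
        mask = groups == name
        km = KaplanMeierFitter()
        km.fit(t[mask], e[mask], label=name)
        cur = km.survival_function_.reset_index()
        cur.columns = ["time", "survival"]
        cur["group"] = name
        curves.append(cur)
    res = logrank_test(t[groups == "low"], t[groups == "high"],
                       e[groups == "low"], e[groups == "high"])
    return KmSplit(groups=groups, log_rank_p=float(res.p_value),
                   curves=pd.concat(curves, ignore_index=True),
                   median_hazard=med, n_ties_at_median=n_ties)


# ---------------------------------------------------------------------------
# Time-dependent ROC
# ---------------------------------------------------------------------------

def censoring_survival(time: np.ndarray, event: np.ndarray) -> KaplanMeierFitter:
    """Kaplan-Meier estimate of the censoring distribution G(t)
    (events and censorings swapped)."""
    km = KaplanMeierFitter()
    km.fit(time, 1 - event)
    return km


def time_dependent_auc(time, event, score, horizon: float) -> float:
    """Cumulative/dynamic time-dependent ROC AUC at ``horizon`` with inverse-
    probability-of-censoring weights (timeROC-style).

    Cases: observed events with T <= horizon, weighted 1/G(T-); controls:
    samples still at risk with T > horizon, weighted 1/G(horizon).  The AUC is
    the weighted probability that a case outranks a control (ties count 1/2).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    score = np.asarray(score, dtype=float)
    cases = (time <= horizon) & (event == 1)
    controls = time > horizon
    if not cases.any() or not controls.any():
        raise SurvivalError("need at least one case and one control at horizon")
    G = censoring_survival(time, event)
    g_case = np.array([float(G.predict(t - 1e-9)) for t in time[cases]])
    g_ctrl = float(G.predict(horizon))
    if g_ctrl <= 0 or (g_case <= 0).any():
        raise SurvivalError("censoring survival vanished before the horizon")
    w_case = 1.0 / g_case
    w_ctrl = np.full(int(controls.sum()), 1.0 / g_ctrl)
    s_case = score[cases]
    s_ctrl = score[controls]
    wins = (s_case[:, None] > s_ctrl[None, :]).astype(float)
    wins += 0.5 * (s_case[:, None] == s_ctrl[None, :])
    weights = w_case[:, None] * w_ctrl[None, :]
    return float((wins * weights).sum() / weights.sum())


# ---------------------------------------------------------------------------
# Repeated hold-out
# ---------------------------------------------------------------------------

MODEL_NAMES = ("genes", "covariates", "genes+covariates")


def repeated_holdout(
    records: pd.DataFrame,
    expression: pd.DataFrame,
    genes: list[str] | None = None,
    n_repeats: int = DEFAULT_N_REPEATS,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    horizon: float = DEFAULT_HORIZON_YEARS,
    seed: int = 0,
    selection_p: float = DEFAULT_SELECTION_P,
) -> pd.DataFrame:
    """Stratified (by event status) repeated train/test evaluation.

    Per repeat: re-screen genes on the training fold only, fit genes-only /
    covariates-only / genes+covariates Cox models on it, predict test-fold
    linear predictors, and compute the time-dependent AUC at ``horizon`` for
    each.  Repeats whose folds have < 2 events, or no case/control at the
    horizon, are skipped and recorded with NaN AUCs.
    """
    from sklearn.model_selection import train_test_split

    genes = list(genes) if genes is not None else list(expression.index)
    cov_all = _encode_covariates(records, use_gender=True)
    ids = np.array(cov_all.index)
    event = records.loc[ids, "event"].astype(int).to_numpy()
    expr = expression.loc[genes, ids].astype(float)
    expr = pd.DataFrame(np.vstack([rank_inverse_normal(expr.loc[g]) for g in genes]),
                        index=genes, columns=ids)
    rows = []
    root = np.random.SeedSequence(int(seed) % 2**31)
    repeat_seeds = root.generate_state(n_repeats)
    for rep in range(n_repeats):
        rep_seed = int(repeat_seeds[rep]) % 2**31
        train_ids, test_ids = train_test_split(
            ids, train_size=train_fraction, random_state=rep_seed, stratify=event)
        row = {"repeat": rep, "skipped": False, "n_selected": 0}
        try:
            train_rec = records.loc[train_ids]
            if int(train_rec["event"].sum()) < 2 or int(
                    records.loc[test_ids, "event"].sum()) < 1:
                raise SurvivalError("too few events in a fold")
            screen = screen_genes(train_rec, expr[train_ids], genes,
                                  selection_p=selection_p, normalize=False)
            row["n_selected"] = len(screen.selected)
            base_tr = pd.DataFrame({
                "time": records.loc[train_ids, "time"].astype(float),
                "event": records.loc[train_ids, "event"].astype(int),
            }).join(cov_all.loc[train_ids])
            designs = {
                "genes": screen.selected,
                "covariates": [],
                "genes+covariates": screen.selected,
            }
            t_test = records.loc[test_ids, "time"].astype(float).to_numpy()
            e_test = records.loc[test_ids, "event"].astype(int).to_numpy()
            for name in MODEL_NAMES:
                use_cov = "covariates" in name
                use_genes = screen.selected if "genes" in name else []
                if not use_genes and not use_cov:
                    row[name] = np.nan
                    continue
                df = base_tr[["time", "event"]].copy()
                if use_cov:
                    df = df.join(cov_all.loc[train_ids])
                for g in use_genes:
                    df[g] = expr.loc[g, train_ids].to_numpy()
                if df.shape[1] <= 2:  # no predictors (empty selection)
                    row[name] = np.nan
                    continue
                cph, _ = _fit_cox_ridge_fallback(df)
                feats = [c for c in df.columns if c not in ("time", "event")]
                X_test = pd.DataFrame(index=test_ids)
                if use_cov:
                    X_test = X_test.join(cov_all.loc[test_ids])
                for g in use_genes:
                    X_test[g] = expr.loc[g, test_ids].to_numpy()
                lp = X_test[feats].to_numpy() @ cph.params_[feats].to_numpy()
                row[name] = time_dependent_auc(t_test, e_test, lp, horizon)
        except SurvivalError as err:
            logger.info("repeat %d skipped: %s", rep, err)
            row.update({"skipped": True,
                        **{name: np.nan for name in MODEL_NAMES}})
        rows.append(row)
    return pd.DataFrame(rows).set_index("repeat")
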