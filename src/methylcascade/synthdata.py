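"""Synthetic methylome cohorts with planted structure.

The generator emulates the statistical shape of Illumina 450K pan-cancer
cohorts: per-probe baselines drawn from a bimodal Beta mixture (most CpGs sit
near fully methylated or fully unmethylated), tissue-specific baseline offsets
so tissue identity is learnable, planted cancer-associated hyper-/hypo-
methylation on a known probe subset (effects are planted on the M scale and
mapped back through the inverse logit2 so they align with the differential-
methylation threshold), Beta-distributed sampling noise, optional missingness,
batch-shifted "independent" cohorts with attenuated adenoma samples, and
paired expression with exponential proportional-hazards survival outcomes.

Every operation draws from its own RNG stream seeded from
``(config.seed, operation name)``, so identical configs give bit-identical
output and adding operations never perturbs existing fixtures.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .annotation import GenomicAnnotation
from .preprocess import beta_to_m, m_to_beta

# Fixed generator internals (not part of the stated cohort regime; see docs).
_NOISE_CONCENTRATION = 100.0   # Beta noise around each expected beta
_TISSUE_MARKER_FRACTION = 0.05  # fraction of probes carrying a tissue offset
_TISSUE_OFFSET_SD = 1.5         # M-scale SD of tissue baseline offsets
_BETA_FLOOR = 1e-6
_BASELINE_HAZARD = np.log(2.0) / 5.0  # median 5-year survival at linear predictor 0


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Cohort regime.

    Defaults follow the pan-cancer 450K setting the pipeline targets: a
    normal-sample fraction of 0.135 per tissue, a planted cancer effect of 3
    on the M scale (comfortably above the differential-methylation threshold
    of 2), and a bimodal beta baseline.
    """

    n_tissues: int = 3
    n_cancer_per_tissue: int = 173
    n_normal_per_tissue: int = 27
    n_probes: int = 2000
    n_informative_per_tissue: int = 20
    effect_size_m: float = 3.0
    low_mode_beta: float = 0.2
    high_mode_beta: float = 0.8
    concentration: float = 40.0
    missing_rate: float = 0.0
    batch_shift_m: float = 0.0
    adenoma_fraction_of_effect: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_tissues, self.n_cancer_per_tissue, self.n_probes) < 1:
            raise SimulationError("counts must be positive")
        if self.n_normal_per_tissue < 0 or self.n_informative_per_tissue < 0:
            raise SimulationError("counts must be non-negative")
        if self.n_informative_per_tissue * self.n_tissues > self.n_probes:
            raise SimulationError(
                "n_informative_per_tissue * n_tissues exceeds n_probes")
        for name in ("low_mode_beta", "high_mode_beta"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise SimulationError(f"{name} must lie in (0, 1), got {v}")
        if self.concentration <= 0:
            raise SimulationError("concentration must be > 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise SimulationError("missing_rate must lie in [0, 1)")
        if not 0.0 <= self.adenoma_fraction_of_effect <= 1.0:
            raise SimulationError("adenoma_fraction_of_effect must lie in [0, 1]")


@dataclass
class SimulatedCohort:
    beta: pd.DataFrame              # probes x samples
    metadata: pd.DataFrame          # indexed by sample_id
    truth: dict[str, dict[str, int]]  # tissue -> {probe_id: +1/-1}
    config: SimConfig
    n_masked: int = 0
    model: dict = field(default_factory=dict, repr=False)  # generative state

    def __post_init__(self) -> None:
        probe_set = set(self.beta.index)
        for tissue, probes in self.truth.items():
            if not set(probes) <= probe_set:
                raise SimulationError(f"truth probes for {tissue} not in matrix")
        if set(self.metadata.index) != set(self.beta.columns):
            raise SimulationError("metadata samples do not match matrix columns")


def _rng(seed: int, operation: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % 2**31, zlib.crc32(operation.encode())]))


def _clip_beta(beta: np.ndarray) -> np.ndarray:
    return np.clip(beta, _BETA_FLOOR, 1.0 - _BETA_FLOOR)


def _sample_beta_noise(rng: np.random.Generator, mean_beta: np.ndarray) -> np.ndarray:
    """Beta-distributed observation around each expected beta value."""
    mu = _clip_beta(mean_beta)
    a = mu * _NOISE_CONCENTRATION
    b = (1.0 - mu) * _NOISE_CONCENTRATION
    return _clip_beta(rng.beta(a, b))


def _build_generative_model(config: SimConfig) -> dict:
    rng = _rng(config.seed, "model")
    n_probes, n_tissues = config.n_probes, config.n_tissues
    probe_ids = [f"cg{i:08d}" for i in range(n_probes)]
    tissues = [f"tissue{t + 1:02d}" for t in range(n_tissues)]

    # bimodal baseline on the beta scale -> M scale
    modes = np.where(rng.random(n_probes) < 0.5,
                     config.low_mode_beta, config.high_mode_beta)
    baseline_beta = _clip_beta(
        rng.beta(modes * config.concentration, (1.0 - modes) * config.concentration))
    baseline_m = np.log2(baseline_beta / (1.0 - baseline_beta))

    # tissue-specific offsets on a small probe subset per tissue
    n_markers = max(1, int(round(_TISSUE_MARKER_FRACTION * n_probes)))
    tissue_offsets = np.zeros((n_tissues, n_probes))
    for t in range(n_tissues):
        idx = rng.choice(n_probes, size=n_markers, replace=False)
        tissue_offsets[t, idx] = rng.normal(0.0, _TISSUE_OFFSET_SD, size=n_markers)

    # planted cancer-informative probes, disjoint across tissues
    n_inf = config.n_informative_per_tissue
    informative = {}
    if n_inf:
        chosen = rng.choice(n_probes, size=n_inf * n_tissues, replace=False)
        for t, tissue in enumerate(tissues):
            idx = np.sort(chosen[t * n_inf:(t + 1) * n_inf])
            signs = rng.choice([-1, 1], size=n_inf)
            informative[tissue] = {probe_ids[i]: int(s) for i, s in zip(idx, signs)}
    else:
        informative = {tissue: {} for tissue in tissues}

    return {
        "probe_ids": probe_ids,
        "tissues": tissues,
        "baseline_m": baseline_m,
        "tissue_offsets": tissue_offsets,
        "informative": informative,
    }


def _expected_m(model: dict, config: SimConfig, tissue_index: int,
                condition: str, effect_fraction: float = 1.0) -> np.ndarray:
    """Expected M-value profile for one (tissue, condition) cell."""
    m = model["baseline_m"] + model["tissue_offsets"][tissue_index]
    if condition in ("cancer", "adenoma"):
        tissue = model["tissues"][tissue_index]
        scale = config.effect_size_m * effect_fraction
        for probe, sign in model["informative"][tissue].items():
            i = int(probe[2:])
            m[i] = m[i] + sign * scale
    return m


def _draw_samples(rng, model, config, cells, prefix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw samples for a list of (tissue_index, condition, count,
    effect_fraction, m_shift) cells."""
    columns, records = [], []
    blocks = []
    counter = 0
    for tissue_index, condition, count, eff_frac, m_shift in cells:
        if count == 0:
            continue
        exp_m = _expected_m(model, config, tissue_index, condition, eff_frac) + m_shift
        exp_beta = 1.0 / (1.0 + 2.0 ** (-exp_m))
        block = _sample_beta_noise(rng, np.tile(exp_beta[:, None], (1, count)))
        blocks.append(block)
        tissue = model["tissues"][tissue_index]
        for _ in range(count):
            sid = f"{prefix}{counter:05d}"
            counter += 1
            columns.append(sid)
            records.append({
                "sample_id": sid,
                "tissue": tissue,
                "condition": condition,
                "age": float(np.round(rng.normal(63.0, 10.0), 1)),
                "stage": int(rng.integers(1, 5)),
                "gender": str(rng.choice(["F", "M"])),
            })
    beta = pd.DataFrame(np.hstack(blocks), index=model["probe_ids"], columns=columns)
    metadata = pd.DataFrame(records).set_index("sample_id")
    return beta, metadata


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Generate the training-style cohort: per tissue, cancer and normal
    samples with the planted informative-probe shifts applied to cancers."""
    model = _build_generative_model(config)
    rng = _rng(config.seed, "cohort")
    cells = []
    for t in range(config.n_tissues):
        cells.append((t, "cancer", config.n_cancer_per_tissue, 1.0, 0.0))
        cells.append((t, "normal", config.n_normal_per_tissue, 0.0, 0.0))
    beta, metadata = _draw_samples(rng, model, config, cells, prefix="S")
    cohort = SimulatedCohort(beta=beta, metadata=metadata,
                             truth=model["informative"], config=config, model=model)
    if config.missing_rate > 0:
        cohort = inject_missingness(cohort, config.missing_rate, config.seed)
    return cohort


def inject_missingness(cohort: SimulatedCohort, rate: float, seed: int) -> SimulatedCohort:
    """Mask each entry independently with probability ``rate``."""
    if not 0.0 <= rate < 1.0:
        raise SimulationError(f"missing rate must lie in [0, 1), got {rate}")
    beta = cohort.beta.copy()
    if rate > 0:
        rng = _rng(seed, "missingness")
        mask = rng.random(beta.shape) < rate
        vals = beta.to_numpy(dtype=float).copy()
        vals[mask] = np.nan
        beta = pd.DataFrame(vals, index=beta.index, columns=beta.columns)
        n_masked = int(mask.sum())
    else:
        n_masked = 0
    return SimulatedCohort(beta=beta, metadata=cohort.metadata.copy(),
                           truth=cohort.truth, config=cohort.config,
                           n_masked=n_masked, model=cohort.model)


def simulate_external_cohort(
    cohort: SimulatedCohort,
    config: SimConfig | None = None,
    n_cancer_per_tissue: int | None = None,
    n_normal_per_tissue: int | None = None,
    n_adenoma_per_tissue: int = 0,
) -> SimulatedCohort:
    """Draw an "independent" cohort from the same generative model, with
    ``batch_shift_m`` added to every probe on the M scale and optional adenoma
    samples whose planted shift is ``adenoma_fraction_of_effect`` of the
    cancer effect."""
    config = config or cohort.config
    if not cohort.model:
        raise SimulationError("cohort carries no generative model state")
    model = cohort.model
    n_cancer = (config.n_cancer_per_tissue if n_cancer_per_tissue is None
                else n_cancer_per_tissue)
    n_normal = (config.n_normal_per_tissue if n_normal_per_tissue is None
                else n_normal_per_tissue)
    rng = _rng(config.seed, "external")
    shift = config.batch_shift_m
    cells = []
    for t in range(len(model["tissues"])):
        cells.append((t, "cancer", n_cancer, 1.0, shift))
        cells.append((t, "normal", n_normal, 0.0, shift))
        cells.append((t, "adenoma", n_adenoma_per_tissue,
                      config.adenoma_fraction_of_effect, shift))
    beta, metadata = _draw_samples(rng, model, config, cells, prefix="EXT")
    return SimulatedCohort(beta=beta, metadata=metadata, truth=model["informative"],
                           config=config, model=model)


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def simulate_annotation(config: SimConfig) -> tuple[GenomicAnnotation, pd.DataFrame]:
    """Place probes and genes on two synthetic chromosomes.

    Roughly one third of probes land inside gene bodies, one third in the
    1500-bp strand-aware promoter window, and one third in neither.  Returns
    the annotation plus the ground-truth probe->gene table
    (probe_id, gene_id, reason) with reason in {body, promoter, none}.
    """
    rng = _rng(config.seed, "annotation")
    n_probes = config.n_probes
    probe_ids = [f"cg{i:08d}" for i in range(n_probes)]
    n_genes = max(2, int(np.ceil(n_probes / 3)))

    genes, gene_layout = [], []
    chroms = ["chr1", "chr2"]
    positions = {c: 10_000 for c in chroms}
    for g in range(n_genes):
        chrom = chroms[g % 2]
        start = positions[chrom]
        length = int(rng.integers(2_000, 20_000))
        strand = str(rng.choice(["+", "-"]))
        biotype = str(rng.choice(["protein_coding", "lncRNA", "other"],
                                 p=[0.7, 0.2, 0.1]))
        genes.append({"gene_id": f"G{g:05d}", "chrom": chrom, "start": start,
                      "end": start + length, "strand": strand,
                      "biotype": biotype, "name": f"GENE{g}"})
        gene_layout.append(genes[-1])
        gap = int(rng.integers(5_000, 20_000))
        positions[chrom] = start + length + 1_600 + gap + 1_600

    probes, truth = [], []
    for i, pid in enumerate(probe_ids):
        gene = gene_layout[i % n_genes]
        kind = ("body", "promoter", "none")[i % 3]
        if kind == "body":
            pos = int(rng.integers(gene["start"], gene["end"]))
            truth.append((pid, gene["gene_id"], "body"))
        elif kind == "promoter":
            offset = int(rng.integers(1, 1_501))  # 1..1500 bp upstream of the TSS
            if gene["strand"] == "+":
                pos = gene["start"] - offset
            else:
                pos = (gene["end"] - 1) + offset
            truth.append((pid, gene["gene_id"], "promoter"))
        else:
            pos = gene["end"] + 1_600 + int(rng.integers(0, 3_000))
            truth.append((pid, "", "none"))
        probes.append({"probe_id": pid, "chrom": gene["chrom"], "pos": pos})

    annotation = GenomicAnnotation(probes=pd.DataFrame(probes),
                                   genes=pd.DataFrame(genes))
    truth_df = pd.DataFrame(truth, columns=["probe_id", "gene_id", "reason"])
    return annotation, truth_df


# ---------------------------------------------------------------------------
# Expression and survival
# ---------------------------------------------------------------------------

def simulate_expression(metadata: pd.DataFrame, n_genes: int = 100,
                        seed: int = 0) -> pd.DataFrame:
    """Gene-by-sample expression matrix on an arbitrary continuous scale
    (the survival screen rank-normalizes it anyway)."""
    rng = _rng(seed, "expression")
    gene_ids = [f"G{g:05d}" for g in range(n_genes)]
    vals = rng.normal(8.0, 2.0, size=(n_genes, len(metadata)))
    return pd.DataFrame(vals, index=gene_ids, columns=metadata.index)


def simulate_survival(
    metadata: pd.DataFrame,
    expression: pd.DataFrame,
    expression_effects: dict[str, float],
    censor_rate: float = 0.3,
    seed: int = 0,
    age_effect: float = 0.02,
    stage_effect: float = 0.3,
) -> pd.DataFrame:
    """Attach exponential proportional-hazards survival outcomes.

    log-hazard = sum_g effect_g * z(expression_g) + age_effect*(age-63)
    + stage_effect*(stage-2.5); censoring is independent exponential, with the
    rate solved so the expected censored fraction is ``censor_rate``.
    Returns a metadata copy with ``time`` (years) and ``event`` columns.
    """
    if not 0.0 <= censor_rate < 1.0:
        raise SimulationError(f"censor_rate must lie in [0, 1), got {censor_rate}")
    unknown = set(expression_effects) - set(expression.index)
    if unknown:
        raise SimulationError(f"effects refer to genes not in expression: {unknown}")
    for g, e in expression_effects.items():
        if not np.isfinite(e):
            raise SimulationError(f"non-finite effect for gene {g}")
    rng = _rng(seed, "survival")
    md = metadata.copy()
    lp = np.zeros(len(md))
    for gene, effect in expression_effects.items():
        x = expression.loc[gene, md.index].to_numpy(dtype=float)
        sd = x.std()
        z = (x - x.mean()) / (sd if sd > 0 else 1.0)
        lp += effect * z
    lp += age_effect * (md["age"].to_numpy(dtype=float) - 63.0)
    lp += stage_effect * (md["stage"].to_numpy(dtype=float) - 2.5)

    rates = _BASELINE_HAZARD * np.exp(lp)
    event_time = rng.exponential(1.0 / rates)
    if censor_rate > 0:
        # P(censored | lambda_i) = mu / (lambda_i + mu); solve mu so the
        # cohort-average censored fraction matches the request
        from scipy.optimize import brentq
        def _mean_censored(mu):
            return float(np.mean(mu / (rates + mu))) - censor_rate
        hi = rates.max() * censor_rate / (1.0 - censor_rate) + 1e-12
        censor_hazard = brentq(_mean_censored, 1e-12, max(hi, 1e-6))
        censor_time = rng.exponential(1.0 / censor_hazard, size=len(md))
    else:
        censor_time = np.full(len(md), np.inf)
    md["time"] = np.minimum(event_time, censor_time)
    md["event"] = (event_time <= censor_time).astype(int)
    return md


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_cohort(cohort: SimulatedCohort, outdir) -> dict[str, str]:
    """Write beta matrix, metadata and truth table as TSV; returns paths."""
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["beta"] = str(outdir / "beta.tsv")
    cohort.beta.to_csv(paths["beta"], sep="\t", index_label="probe_id")
    paths["metadata"] = str(outdir / "metadata.tsv")
    cohort.metadata.to_csv(paths["metadata"], sep="\t", index_label="sample_id")
    rows = [(t, p, s) for t, probes in cohort.truth.items()
            for p, s in sorted(probes.items())]
    paths["truth"] = str(outdir / "truth.tsv")
    pd.DataFrame(rows, columns=["tissue", "probe_id", "effect_sign"]).to_csv(
        paths["truth"], sep="\t", index=False)
    return paths
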