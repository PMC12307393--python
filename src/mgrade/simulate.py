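"""Synthetic cohort generator with the statistical structure the pipeline assumes.

The generator plants a two-class expression signature (a latent high-risk and
low-risk class), proportional-hazards survival driven by the latent class,
independent censoring, intermediate-grade (G2) relabeling, and optional
per-batch strictly monotone distortions of the expression values. The latent
class is the hidden ground truth: pipeline stages never see it, tests do.

It deliberately does not mimic real-cohort marginal distributions, platform
noise, or gene-gene correlation beyond the planted signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .datatypes import ClinicalTable, ExpressionMatrix, Platform

__all__ = [
    "SimulationSpec",
    "SyntheticCohort",
    "GenomicFeatureSpec",
    "generate_cohort",
    "apply_monotone_batch_distortion",
    "generate_genomic_features",
    "DEFAULT_SPEC",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of the synthetic cohort.

    Expression is baseline + class-dependent shift on the signal genes +
    Gaussian noise, on a log2-like scale. Survival is exponential with the
    hazard multiplied by ``hazard_ratio`` for latent-high samples; censoring
    combines an independent exponential with an administrative cutoff.
    """

    n_samples: int = 400
    n_genes: int = 2000
    n_signal_up: int = 30       # genes up in latent-high
    n_signal_down: int = 30     # genes up in latent-low
    effect_size: float = 1.5    # mean log2 shift between latent classes
    noise_sd: float = 1.0       # per-gene Gaussian sd
    high_fraction: float = 0.5
    intermediate_fraction: float = 0.2  # fraction relabeled G2, both classes
    hazard_ratio: float = 3.0
    baseline_hazard: float = 1.0 / 1500.0  # events/day for latent-low
    censor_rate: float = 0.25   # target fraction censored by the random mechanism
    admin_cutoff: float = 3000.0  # days; administrative censoring horizon
    n_batches: int = 1
    seed: int = 0
    platform: Platform = Platform.MICROARRAY

    def __post_init__(self) -> None:
        for name in ("high_fraction", "intermediate_fraction", "censor_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be > 0")
        if self.n_signal_up + self.n_signal_down > self.n_genes:
            raise ValueError("more signal genes than genes")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")


#: Canonical fixture used throughout the test battery.
DEFAULT_SPEC = SimulationSpec()


@dataclass
class SyntheticCohort:
    """A generated cohort plus the hidden truth used only for evaluation."""

    expr: ExpressionMatrix
    clin: ClinicalTable
    latent_class: pd.Series  # per-sample "high"/"low"; tests only
    signal_up: list[str] = field(default_factory=list)
    signal_down: list[str] = field(default_factory=list)


def generate_cohort(spec: SimulationSpec) -> SyntheticCohort:
    """Draw a cohort from ``spec``. Same spec (incl. seed) => identical output."""
    rng = np.random.default_rng(spec.seed)
    n, g = spec.n_samples, spec.n_genes

    sample_ids = [f"S{i:04d}" for i in range(n)]
    gene_ids = [f"GENE{i:04d}" for i in range(g)]
    up_genes = gene_ids[: spec.n_signal_up]
    down_genes = gene_ids[spec.n_signal_up: spec.n_signal_up + spec.n_signal_down]

    latent_high = rng.random(n) < spec.high_fraction
    latent = pd.Series(np.where(latent_high, "high", "low"), index=sample_ids, name="latent_class")

    baseline = rng.normal(8.0, 1.5, size=g)  # per-gene baseline log2 level
    values = baseline[:, None] + rng.normal(0.0, spec.noise_sd, size=(g, n))
    half = spec.effect_size / 2.0
    up_idx = np.arange(spec.n_signal_up)
    down_idx = np.arange(spec.n_signal_up, spec.n_signal_up + spec.n_signal_down)
    values[np.ix_(up_idx, np.arange(n))] += np.where(latent_high, half, -half)[None, :]
    values[np.ix_(down_idx, np.arange(n))] += np.where(latent_high, -half, half)[None, :]

    batch_labels = pd.Series(
        [f"batch{i % spec.n_batches}" for i in range(n)], index=sample_ids, name="batch"
    )
    expr = ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids),
        spec.platform,
        batch_labels,
    )

    # histological grade: concordant with latent class except a random
    # intermediate_fraction relabeled G2 (drawn from both classes)
    grade = np.where(latent_high, "G3", "G1").astype(object)
    g2_mask = rng.random(n) < spec.intermediate_fraction
    grade[g2_mask] = "G2"

    # exponential survival under proportional hazards
    hazard = spec.baseline_hazard * np.where(latent_high, spec.hazard_ratio, 1.0)
    event_time = rng.exponential(1.0 / hazard)
    if spec.censor_rate > 0:
        # exponential censoring calibrated so that, marginally, roughly
        # censor_rate of samples are censored before their event
        mean_hazard = spec.baseline_hazard * (
            spec.high_fraction * spec.hazard_ratio + (1 - spec.high_fraction)
        )
        censor_hazard = mean_hazard * spec.censor_rate / max(1e-12, 1 - spec.censor_rate)
        censor_time = rng.exponential(1.0 / censor_hazard, size=n)
    else:
        censor_time = np.full(n, np.inf)
    censor_time = np.minimum(censor_time, spec.admin_cutoff)
    os_time = np.minimum(event_time, censor_time)
    os_event = (event_time <= censor_time).astype(int)

    clin = ClinicalTable(pd.DataFrame(
        {
            "grade": grade,
            "os_time": os_time,
            "os_event": os_event,
            # stage loosely tracks latent risk so stage-association tests
            # have signal to find
            "stage": _draw_stages(rng, latent_high),
            "cohort": batch_labels.values,
            "lymph_node_status": np.where(
                rng.random(n) < np.where(latent_high, 0.6, 0.3), "positive", "negative"
            ),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    ))
    return SyntheticCohort(expr, clin, latent, list(up_genes), list(down_genes))


def _draw_stages(rng: np.random.Generator, latent_high: np.ndarray) -> np.ndarray:
    stages = np.array(["I", "II", "III", "IV"])
    p_low = np.array([0.45, 0.35, 0.15, 0.05])
    p_high = np.array([0.15, 0.30, 0.35, 0.20])
    out = np.empty(latent_high.shape, dtype=object)
    for i, hi in enumerate(latent_high):
        out[i] = rng.choice(stages, p=p_high if hi else p_low)
    return out


def apply_monotone_batch_distortion(
    expr: ExpressionMatrix,
    transforms: Mapping[str, Callable[[np.ndarray], np.ndarray]],
    n_probe: int = 64,
) -> ExpressionMatrix:
    """Apply a strictly increasing per-batch transform to every sample's values.

    Within-sample gene ordering is unchanged by construction, which is the
    property the rank-based classifier relies on. Each transform is probed on
    a grid spanning the batch's data range; a non-increasing transform is
    rejected.
    """
    if expr.batch is None:
        raise ValueError("expression matrix has no batch labels")
    values = expr.values.copy()
    for batch_name, fn in transforms.items():
        cols = expr.batch[expr.batch == batch_name].index
        if len(cols) == 0:
            continue
        block = values.loc[:, cols].to_numpy()
        finite = block[np.isfinite(block)]
        if finite.size:
            probe = np.linspace(finite.min(), finite.max(), n_probe)
            out = np.asarray(fn(probe), dtype=float)
            if not np.all(np.diff(out) > 0):
                raise ValueError(f"transform for batch {batch_name!r} is not strictly increasing")
        values.loc[:, cols] = fn(block)
    return ExpressionMatrix(values, expr.platform, expr.batch)


@dataclass(frozen=True)
class GenomicFeatureSpec:
    """Rates for the synthetic mutation / copy-number / protein tables.

    ``mutation_rates`` maps gene -> (rate in latent-high, rate in latent-low).
    ``cna_events`` maps (chrom, start, end, kind) -> (rate_high, rate_low)
    with kind in {"amp", "del"}. ``protein_means`` maps protein ->
    (mean_high, mean_low); proteins are Gaussian with unit sd.
    """

    mutation_rates: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    cna_events: Mapping[tuple[str, int, int, str], tuple[float, float]] = field(default_factory=dict)
    protein_means: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    background_mutation_genes: int = 20
    background_mutation_rate: float = 0.05
    ploidy: float = 2.0

    def __post_init__(self) -> None:
        for name, rates in [("mutation_rates", self.mutation_rates)]:
            for key, (rh, rl) in rates.items():
                if not (0 <= rh <= 1 and 0 <= rl <= 1):
                    raise ValueError(f"{name}[{key!r}] rates must be in [0, 1]")


def generate_genomic_features(
    cohort: SyntheticCohort, spec: GenomicFeatureSpec, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw (MutationTable, SegmentTable, ProteinTable) for a cohort.

    Mutations are Bernoulli per gene with class-specific rates (plus an
    optional uniform background gene set); segments carry total copy number 0
    (deletion events), 2*ploidy (amplifications) or ploidy elsewhere; protein
    levels are Gaussian with class-specific means.
    """
    # keyed stream: never collides with the expression/survival stream even
    # when the same seed integer is reused for cohort and features
    rng = np.random.default_rng([seed, 0x6D757461])
    samples = cohort.clin.sample_ids
    is_high = (cohort.latent_class == "high").to_numpy()

    mut_rows = []
    rates = dict(spec.mutation_rates)
    for i in range(spec.background_mutation_genes):
        rates.setdefault(f"BG{i:03d}", (spec.background_mutation_rate, spec.background_mutation_rate))
    for gene, (rate_hi, rate_lo) in rates.items():
        p = np.where(is_high, rate_hi, rate_lo)
        mutated = rng.random(len(samples)) < p
        for s, m in zip(samples, mutated):
            if m:
                mut_rows.append((s, gene, "Missense_Mutation", round(float(rng.uniform(0.1, 0.9)), 3)))
    muts = pd.DataFrame(mut_rows, columns=["sample_id", "gene", "variant_classification", "vaf"])

    seg_rows = []
    for (chrom, start, end, kind), (rate_hi, rate_lo) in spec.cna_events.items():
        p = np.where(is_high, rate_hi, rate_lo)
        hit = rng.random(len(samples)) < p
        for s, h in zip(samples, hit):
            if h:
                cn = 0 if kind == "del" else int(round(2 * spec.ploidy))
                seg_rows.append((s, chrom, start, end, cn, spec.ploidy))
    segs = pd.DataFrame(
        seg_rows, columns=["sample_id", "chrom", "start", "end", "total_cn", "ploidy"]
    )

    prot = {}
    for protein, (mu_hi, mu_lo) in spec.protein_means.items():
        prot[protein] = np.where(is_high, mu_hi, mu_lo) + rng.normal(size=len(samples))
    proteins = pd.DataFrame(prot, index=pd.Index(samples, name="sample_id"))
    return muts, segs, proteins
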