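"""Synthetic NSCLC-like immunotherapy cohorts with planted ground truth.

The generator emulates the statistical structure the derivation pipeline
assumes: negative-binomial RNA-seq counts with an "immune" gene program whose
activity is elevated in responders, a "keratin" program elevated in
non-responders, checkpoint genes co-regulated with the immune program,
censored progression-free survival whose hazard falls with the true composite
score, PD-L1 TPS as a noisy monotone readout of checkpoint activity, TMB
independent of the score, and tumor purity positively coupled to the keratin
program. Everything is reproducible from a single seed.

Program activities carry per-sample lognormal heterogeneity (patients differ
in how inflamed or keratinized their tumor is beyond the R/NR shift), which is
what makes genes of one program co-expressed — the feature K-means pattern
discovery relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import ClinicalTable, ExpressionMatrix, GeneSet, GeneSetCollection, make_clinical
from .scoring import CHECKPOINT_GENES, checkpoint_gene_set

__all__ = ["SimulationConfig", "TruthRecord", "simulate_cohort", "simulate_signature_library"]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of a simulated cohort.

    Defaults mirror an advanced-NSCLC checkpoint-blockade cohort: ~40%
    responders, a hundred-odd patients, two 60-gene response-associated
    expression programs of moderate effect (1.5 log2 units), overdispersed
    counts, and PFS censored at 30%.
    """

    n_samples: int = 120
    n_genes: int = 2000
    n_immune_genes: int = 60
    n_keratin_genes: int = 60
    include_checkpoint_genes: bool = True
    n_signatures: int = 100
    signatures_overlapping_truth: int = 40
    effect_size: float = 1.5          # log2-fold program shift between R and NR
    nb_dispersion: float = 0.2        # NB: var = mu + dispersion * mu^2
    base_mean_log_range: tuple[float, float] = (2.0, 10.0)  # log2 units
    responder_fraction: float = 0.4
    survival_beta: float = -1.0       # log-hazard per unit (centered) true score
    baseline_hazard: float = 0.05     # events per month
    censoring_rate: float = 0.3
    seed: int = 42
    #: Which genes belong to which program (and their baseline abundance) is a
    #: property of the biology, not of the patient sample: cohorts simulated
    #: with different ``seed`` but the same architecture seed share gene roles,
    #: so signatures derived on one cohort transfer to another.
    gene_architecture_seed: int = 20240101
    # Realism knobs (fixed generator design choices):
    activity_sd: float = 0.9          # per-sample program-activity noise, log2 units
    checkpoint_coupling: float = 0.6  # checkpoint activity = coupling * immune + noise
    checkpoint_noise_sd: float = 0.3
    # Transcriptional programs have a tightly co-regulated core and a loosely
    # coupled periphery; periphery genes keep the full mean shift but track the
    # per-sample program activity weakly and are more overdispersed.
    program_core_fraction: float = 0.42
    periphery_coupling: float = 0.15
    periphery_dispersion_multiplier: float = 10.0
    # Program core genes are abundant marker genes (CD8A/KRT5-like), so their
    # baseline expression is drawn from the upper half of the range.
    core_mean_log_range: tuple[float, float] = (5.0, 10.0)

    def __post_init__(self) -> None:
        n_program = (
            self.n_immune_genes + self.n_keratin_genes + 7 * self.include_checkpoint_genes
        )
        if n_program > self.n_genes:
            raise ValueError("program genes exceed n_genes")
        if not 0 < self.responder_fraction < 1:
            raise ValueError("responder_fraction must be in (0, 1)")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must be in [0, 1)")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.n_samples < 8:
            raise ValueError("n_samples too small for a cohort")

    def with_(self, **overrides) -> "SimulationConfig":
        return replace(self, **overrides)


@dataclass
class TruthRecord:
    """Planted ground truth of a simulated cohort."""

    immune_genes: list[str]
    keratin_genes: list[str]
    checkpoint_genes: list[str]
    immune_core_genes: list[str]
    keratin_core_genes: list[str]
    immune_activity: pd.Series
    keratin_activity: pd.Series
    checkpoint_activity: pd.Series
    true_score: pd.Series            # immune + checkpoint - keratin activity
    responder: pd.Series             # "R"/"NR"
    event_times: pd.Series           # uncensored
    null_genes: list[str] = field(default_factory=list)


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion) -> np.ndarray:
    """NB(mu, var = mu + dispersion*mu^2) via the size/prob parameterization.

    ``dispersion`` may be scalar or broadcastable against ``mu`` (per-gene).
    """
    size = 1.0 / np.asarray(dispersion, dtype=float)
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def simulate_cohort(config: SimulationConfig) -> tuple[ExpressionMatrix, ClinicalTable, TruthRecord]:
    """Simulate (counts, clinical, truth) for one cohort."""
    rng = np.random.default_rng(config.seed)
    arch_rng = np.random.default_rng(config.gene_architecture_seed)
    n, g = config.n_samples, config.n_genes

    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    n_r = int(round(n * config.responder_fraction))
    responder = np.array(["R"] * n_r + ["NR"] * (n - n_r))
    rng.shuffle(responder)
    # RECIST classes: responders mostly PR with occasional CR; non-responders
    # SD-dominant (matching typical advanced-NSCLC response distributions).
    response = np.where(
        responder == "R",
        np.where(rng.random(n) < 0.1, "CR", "PR"),
        np.where(rng.random(n) < 0.8, "SD", "PD"),
    )

    gene_ids = [f"GENE{i + 1:05d}" for i in range(g)]
    picked = arch_rng.choice(g, size=config.n_immune_genes + config.n_keratin_genes, replace=False)
    immune_idx = np.sort(picked[: config.n_immune_genes])
    keratin_idx = np.sort(picked[config.n_immune_genes :])
    ckpt_idx = np.array([], dtype=int)
    if config.include_checkpoint_genes:
        ckpt_symbols = sorted(checkpoint_gene_set().genes)
        free = np.setdiff1d(np.arange(g), picked)
        ckpt_idx = np.sort(arch_rng.choice(free, size=len(ckpt_symbols), replace=False))
        for pos, symbol in zip(ckpt_idx, ckpt_symbols):
            gene_ids[pos] = symbol

    is_r = responder == "R"
    immune_noise = rng.normal(0.0, config.activity_sd, n)
    keratin_noise = rng.normal(0.0, config.activity_sd, n)
    immune_act = config.effect_size * is_r + immune_noise
    keratin_act = config.effect_size * (~is_r) + keratin_noise
    ckpt_act = config.checkpoint_coupling * immune_act + rng.normal(
        0.0, config.checkpoint_noise_sd, n
    )
    true_score = immune_act + ckpt_act - keratin_act

    # Core genes track the per-sample program activity tightly; periphery
    # genes carry the same mean shift but only weakly follow the activity and
    # are more overdispersed (looser co-regulation).
    n_imm_core = int(round(config.program_core_fraction * config.n_immune_genes))
    n_ker_core = int(round(config.program_core_fraction * config.n_keratin_genes))
    imm_loading = np.where(np.arange(config.n_immune_genes) < n_imm_core,
                           1.0, config.periphery_coupling)
    ker_loading = np.where(np.arange(config.n_keratin_genes) < n_ker_core,
                           1.0, config.periphery_coupling)

    lo, hi = config.base_mean_log_range
    base = arch_rng.uniform(lo, hi, g)
    core_lo, core_hi = config.core_mean_log_range
    core_idx = np.concatenate([immune_idx[:n_imm_core], keratin_idx[:n_ker_core]])
    base[core_idx] = arch_rng.uniform(core_lo, core_hi, core_idx.size)
    log2_mu = np.tile(base[:, None], (1, n))
    log2_mu[immune_idx] += (
        config.effect_size * is_r[None, :] + imm_loading[:, None] * immune_noise[None, :]
    )
    log2_mu[keratin_idx] += (
        config.effect_size * (~is_r)[None, :] + ker_loading[:, None] * keratin_noise[None, :]
    )
    if ckpt_idx.size:
        log2_mu[ckpt_idx] += ckpt_act
    dispersion = np.full((g, 1), config.nb_dispersion)
    periphery = np.concatenate([immune_idx[n_imm_core:], keratin_idx[n_ker_core:]])
    dispersion[periphery] *= config.periphery_dispersion_multiplier
    counts = _nb_counts(rng, np.exp2(log2_mu), dispersion)

    centered = true_score - true_score.mean()
    hazard = config.baseline_hazard * np.exp(config.survival_beta * centered)
    event_times = rng.exponential(1.0 / hazard)
    censored = rng.random(n) < config.censoring_rate
    pfs_time = np.where(censored, event_times * rng.uniform(0.05, 1.0, n), event_times)
    pfs_time = np.maximum(pfs_time, 1e-3)
    pfs_event = (~censored).astype(int)

    # PD-L1 TPS: noisy monotone transform of checkpoint activity (percent).
    tps_logit = 1.2 * (ckpt_act - ckpt_act.mean()) + rng.normal(0, 1.0, n) - 1.0
    pdl1_tps = np.round(100.0 / (1.0 + np.exp(-tps_logit)), 1)
    # TMB independent of the score (mut/Mb).
    tmb = np.round(rng.gamma(shape=2.0, scale=3.0, size=n), 2)
    # Purity rises with keratin activity (keratinized tumors are tumor-cell rich).
    purity_logit = 0.4 + 0.8 * (keratin_act - keratin_act.mean()) + rng.normal(0, 0.6, n)
    purity = np.clip(1.0 / (1.0 + np.exp(-purity_logit)), 0.02, 0.99)

    expr = ExpressionMatrix(
        pd.DataFrame(counts.astype(float), index=pd.Index(gene_ids, name="gene"), columns=sample_ids),
        "counts",
    )
    clinical = make_clinical(
        pd.DataFrame(
            {
                "response": response,
                "pfs_time": np.round(pfs_time, 3),
                "pfs_event": pfs_event,
                "pdl1_tps": pdl1_tps,
                "tmb": tmb,
                "tumor_purity": np.round(purity, 3),
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    idx = pd.Index(sample_ids, name="sample_id")
    program_all = set(immune_idx) | set(keratin_idx) | set(ckpt_idx)
    truth = TruthRecord(
        immune_genes=[gene_ids[i] for i in immune_idx],
        keratin_genes=[gene_ids[i] for i in keratin_idx],
        checkpoint_genes=[gene_ids[i] for i in ckpt_idx],
        immune_core_genes=[gene_ids[i] for i in immune_idx[:n_imm_core]],
        keratin_core_genes=[gene_ids[i] for i in keratin_idx[:n_ker_core]],
        immune_activity=pd.Series(immune_act, index=idx),
        keratin_activity=pd.Series(keratin_act, index=idx),
        checkpoint_activity=pd.Series(ckpt_act, index=idx),
        true_score=pd.Series(true_score, index=idx),
        responder=pd.Series(responder, index=idx),
        event_times=pd.Series(event_times, index=idx),
        null_genes=[gene_ids[i] for i in range(g) if i not in program_all],
    )
    return expr, clinical, truth


def simulate_signature_library(
    config: SimulationConfig, truth: TruthRecord
) -> GeneSetCollection:
    """A synthetic signature library: a stand-in for a published gene-set
    compendium, with a configured number of sets overlapping the planted
    immune/keratin programs (>= 50% of members drawn from the program) and the
    remainder drawn from null genes. Set sizes are 10-50 genes.
    """
    if config.signatures_overlapping_truth > config.n_signatures:
        raise ValueError("signatures_overlapping_truth exceeds n_signatures")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    null_pool = np.array(truth.null_genes)
    programs = [np.array(truth.immune_genes), np.array(truth.keratin_genes)]
    n_overlap = config.signatures_overlapping_truth
    sets = []
    for i in range(config.n_signatures):
        size = int(rng.integers(10, 51))
        if i < n_overlap:
            prog = programs[i % 2]
            frac = rng.uniform(0.5, 0.9)
            n_prog = min(max(int(np.ceil(frac * size)), 1), prog.size)
            if n_prog < np.ceil(0.5 * size):
                size = int(n_prog / 0.5)  # keep the >=50% overlap guarantee
            members = set(rng.choice(prog, size=n_prog, replace=False))
            members |= set(rng.choice(null_pool, size=max(size - n_prog, 0), replace=False))
        else:
            members = set(rng.choice(null_pool, size=size, replace=False))
        sets.append(GeneSet(f"SIG{i + 1:03d}", "synthetic signature", frozenset(members)))
    return GeneSetCollection(sets)


def truth_gene_sets(truth: TruthRecord) -> tuple[GeneSet, GeneSet]:
    """The planted immune/keratin programs as gene sets (for oracle scoring)."""
    return (
        GeneSet("IMMUNE", "planted immune program", frozenset(truth.immune_genes)),
        GeneSet("KERATIN", "planted keratin program", frozenset(truth.keratin_genes)),
    )
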