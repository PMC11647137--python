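"""The end-to-end signature derivation and scoring pipeline.

Derivation stages (all response-association tests are Wilcoxon rank-sum):

1. ssGSEA-score a signature library over the cohort and keep the top 15
   signatures per direction (up in responders / up in non-responders, p<0.05).
2. Pool the member genes of the selected signatures and keep those
   individually associated with response (p<0.05).
3. Differential expression on counts (median-of-ratios normalization,
   p<0.005 and |log2FC|>1), top 35 per direction.
4. Union of stages 2-3, pseudogene removal (biotype table), then a final
   top-30-per-direction re-screen -> the final gene panel.
5. K-means (k=5) on gene z-scores; the cluster most associated with response
   is the immune pattern, the least the keratin pattern.

Scoring: ssGSEA of the immune pattern, keratin pattern and the fixed 7-gene
checkpoint set, combined as immune + checkpoint - keratin.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import evaluation, patterns, screening, scoring, ssgsea
from .core_io import (
    ClinicalTable,
    ExpressionMatrix,
    GeneSetCollection,
    ValidationError,
)

logger = logging.getLogger("ikcscore")


@dataclass(frozen=True)
class PipelineConfig:
    """Stage parameters; the defaults are the published-analysis preset."""

    preset: str = "published"
    top_k_signatures: int = 15
    top_k_de: int = 35
    top_k_final: int = 30
    p_signature: float = 0.05
    p_gene: float = 0.05
    p_de: float = 0.005
    lfc_de: float = 1.0
    k_patterns: int = 5
    alpha: float = 0.25
    minprop: float = 0.1
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        config = cls(**raw)
        for key, value in raw.items():
            default = getattr(cls(), key)
            if value != default:
                logger.info("config override: %s = %r (default %r)", key, value, default)
        return config

    def to_dict(self) -> dict:
        return asdict(self)

    def with_(self, **overrides) -> "PipelineConfig":
        return replace(self, **overrides)


@dataclass
class DeriveResult:
    """Derived immune/keratin patterns plus per-stage bookkeeping."""

    immune: "patterns.GeneSet"
    keratin: "patterns.GeneSet"
    assignment: patterns.PatternAssignment
    signature_screen: screening.ScreenResult
    gene_screen: screening.ScreenResult
    de: screening.ScreenResult
    final_screen: screening.ScreenResult
    report: dict

    def pattern_collection(self) -> GeneSetCollection:
        return GeneSetCollection([self.immune, self.keratin])


def derive_signatures(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    library: GeneSetCollection,
    config: PipelineConfig = PipelineConfig(),
    biotype_table: Mapping[str, str] | None = None,
) -> DeriveResult:
    """Run the full derivation pipeline on a counts cohort."""
    if expr.value_kind != "counts":
        raise ValidationError("derivation starts from a counts matrix (the DE stage needs counts)")

    logger.info("stage 1: ssGSEA signature screen (%d sets)", len(library))
    scores = ssgsea.score_matrix(expr, library, alpha=config.alpha, normalize=True)
    sig_screen = screening.screen_signatures(
        scores, clinical, top_k=config.top_k_signatures, p_max=config.p_signature
    )
    n_sig_r = len(sig_screen.selected_by_direction(screening.UP_IN_R))
    n_sig_nr = len(sig_screen.selected_by_direction(screening.UP_IN_NR))

    logger.info("stage 2: pooling genes of %d signatures", n_sig_r + n_sig_nr)
    pooled = screening.pool_signature_genes(sig_screen.selected_features, library)
    normalized = screening.normalize_counts(expr)
    gene_screen = screening.screen_gene_candidates(
        normalized, clinical, pooled, top_k=None, p_max=config.p_gene
    )

    logger.info("stage 3: differential expression (%d genes)", expr.n_genes)
    de = screening.differential_expression(
        expr, clinical, top_k=config.top_k_de, p_max=config.p_de, lfc_min=config.lfc_de
    )

    union = sorted(set(gene_screen.selected_features) | set(de.selected_features))
    logger.info("stage 4: union of %d genes; pseudogene filter + final screen", len(union))
    filtered = screening.filter_pseudogenes(union, biotype_table)
    final = screening.screen_gene_candidates(
        normalized, clinical, filtered, top_k=config.top_k_final, p_max=config.p_gene
    )
    final_genes = final.selected_features

    logger.info("stage 5: K-means (k=%d) on %d genes", config.k_patterns, len(final_genes))
    z = patterns.standardize_genes(normalized, final_genes)
    clusters = patterns.kmeans_cluster(z, k=config.k_patterns, seed=config.seed)
    assignment = patterns.label_patterns(clusters, z, clinical)

    report = {
        "config": config.to_dict(),
        "n_signatures_tested": len(library),
        "n_signatures_selected_up_in_R": n_sig_r,
        "n_signatures_selected_up_in_NR": n_sig_nr,
        "n_pooled_genes": len(pooled),
        "n_gene_screen_selected": len(gene_screen.selected_features),
        "n_de_selected_up_in_R": len(de.selected_by_direction(screening.UP_IN_R)),
        "n_de_selected_up_in_NR": len(de.selected_by_direction(screening.UP_IN_NR)),
        "n_union": len(union),
        "n_after_pseudogene_filter": len(filtered),
        "n_final_genes": len(final_genes),
        "n_patterns": int(clusters.nunique()),
        "cluster_sizes": {str(k): v for k, v in assignment.cluster_sizes().items()},
        "cluster_association": {str(k): v for k, v in assignment.association.items()},
        "immune_cluster": assignment.immune,
        "keratin_cluster": assignment.keratin,
        "n_immune_pattern_genes": len(assignment.immune_genes),
        "n_keratin_pattern_genes": len(assignment.keratin_genes),
    }
    return DeriveResult(
        immune=assignment.immune_genes,
        keratin=assignment.keratin_genes,
        assignment=assignment,
        signature_screen=sig_screen,
        gene_screen=gene_screen,
        de=de,
        final_screen=final,
        report=report,
    )


def score_cohort(
    expr: ExpressionMatrix,
    pattern_sets: GeneSetCollection,
    config: PipelineConfig = PipelineConfig(),
) -> pd.DataFrame:
    """Compute the IKC profile of a cohort from IMMUNE/KERATIN pattern sets."""
    for name in ("IMMUNE", "KERATIN"):
        if name not in pattern_sets:
            raise ValidationError(f"pattern collection lacks a set named {name}")
    profile = scoring.compute_components(
        expr,
        pattern_sets["IMMUNE"],
        pattern_sets["KERATIN"],
        scoring.checkpoint_gene_set(),
        alpha=config.alpha,
    )
    scoring.validate_profile(profile)
    return profile


def evaluate_cohort(
    profile: pd.DataFrame,
    clinical: ClinicalTable,
    config: PipelineConfig = PipelineConfig(),
) -> dict:
    """AUC / survival / comparator report for a scored cohort."""
    return evaluation.evaluate_profile(profile, clinical, minprop=config.minprop)
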