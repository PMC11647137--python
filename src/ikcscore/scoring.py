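"""Composite IKC score: Immune + Immune Checkpoint - Keratin.

The three component scores are ssGSEA scores of the immune pattern, the
keratin pattern, and a fixed 7-gene immune checkpoint set. They are normalized
jointly (a single cohort-level ssGSEA call over the 3 x samples score matrix)
so the sum is on one scale, and combined as

    ikc_score = immune_score + checkpoint_score - krt_score

High scores mark an inflamed, checkpoint-expressing, keratin-low tumor — the
phenotype associated with benefit from immune checkpoint blockade.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .core_io import GeneSet, GeneSetCollection, ExpressionMatrix, ValidationError, map_gene_symbols
from .ssgsea import DEFAULT_ALPHA, score_matrix

logger = logging.getLogger("ikcscore")

#: The immune checkpoint gene set (as published, alias symbols included).
CHECKPOINT_GENES = ("PDL1", "PDCD1LG2", "CTLA4", "PDCD1", "LAG3", "HAVCR2", "TIGIT")

PROFILE_COLUMNS = ("immune_score", "krt_score", "checkpoint_score", "ikc_score", "group")


def checkpoint_gene_set(alias_table: Mapping[str, str] | None = None) -> GeneSet:
    """The 7-gene immune checkpoint set, alias-mapped (PDL1 -> CD274)."""
    genes = map_gene_symbols(CHECKPOINT_GENES, alias_table)
    return GeneSet("CHECKPOINT", "immune checkpoint genes", frozenset(genes))


def compute_components(
    expr: ExpressionMatrix,
    immune_set: GeneSet,
    krt_set: GeneSet,
    ckpt_set: GeneSet | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Per-sample component scores and the composite IKC score.

    Returns a DataFrame indexed by sample id with columns immune_score,
    krt_score, checkpoint_score, ikc_score and an (empty) group column; the
    identity ikc = immune + checkpoint - krt holds exactly by construction.
    """
    if ckpt_set is None:
        ckpt_set = checkpoint_gene_set()
    sets = GeneSetCollection([
        GeneSet("IMMUNE", immune_set.description, immune_set.genes),
        GeneSet("KERATIN", krt_set.description, krt_set.genes),
        GeneSet("CHECKPOINT", ckpt_set.description, ckpt_set.genes),
    ])
    scores = score_matrix(expr, sets, alpha=alpha, normalize=True).scores
    profile = pd.DataFrame(index=pd.Index(expr.sample_ids, name="sample_id"))
    profile["immune_score"] = scores.loc["IMMUNE"]
    profile["krt_score"] = scores.loc["KERATIN"]
    profile["checkpoint_score"] = scores.loc["CHECKPOINT"]
    profile["ikc_score"] = (
        profile["immune_score"] + profile["checkpoint_score"] - profile["krt_score"]
    )
    profile["group"] = pd.Series(pd.NA, index=profile.index, dtype="object")
    return profile


def dichotomize(profile: pd.DataFrame, cutoff: float) -> pd.DataFrame:
    """Assign high/low groups by the IKC score; boundary samples go to low."""
    scores = profile["ikc_score"]
    if cutoff < scores.min() or cutoff > scores.max():
        logger.warning(
            "cutoff %.4g outside observed score range [%.4g, %.4g]; one group is empty",
            cutoff, scores.min(), scores.max(),
        )
    out = profile.copy()
    out["group"] = np.where(scores > cutoff, "high", "low")
    return out


def validate_profile(profile: pd.DataFrame, tol: float = 1e-9) -> None:
    """Assert the composite identity ikc = immune + checkpoint - krt."""
    resid = (
        profile["immune_score"] + profile["checkpoint_score"] - profile["krt_score"]
        - profile["ikc_score"]
    )
    if resid.abs().max() > tol:
        raise ValidationError("profile violates ikc = immune + checkpoint - krt")


def write_profile(profile: pd.DataFrame, path) -> None:
    profile.to_csv(path, sep="\t", index_label="sample_id")


def read_profile(path) -> pd.DataFrame:
    profile = pd.read_csv(path, sep="\t", index_col="sample_id")
    validate_profile(profile)
    return profile
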