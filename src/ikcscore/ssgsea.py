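"""Single-sample gene-set enrichment (ssGSEA) scoring.

Per sample, genes are rank-transformed (average ranks at ties, largest
expression = rank N) and an enrichment score (ES) is accumulated as the
integrated difference between the weighted in-set rank step function and the
uniform out-of-set step function, walking genes in decreasing rank order:

    P_in(i)  = sum_{g in S, pos(g) <= i} R_g^alpha / sum_{g in S} R_g^alpha
    P_out(i) = |{g not in S, pos(g) <= i}| / (N - |S|)
    ES       = sum_i (P_in(i) - P_out(i))

Ties in rank are broken by ascending gene symbol so scoring is deterministic.
Because only within-sample ranks enter, the ES is invariant to any strictly
increasing transform of one sample's expression values — per-sample library
size scaling therefore does not affect scores.

Cohort-level normalization divides all scores by the global (max - min) ES of
the score matrix, so a sample's normalized score depends on the cohort it was
scored with (the score cannot be computed for one sample in isolation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core_io import ExpressionMatrix, GeneSet, GeneSetCollection, ValidationError

logger = logging.getLogger("ikcscore")

DEFAULT_ALPHA = 0.25  # canonical ssGSEA rank-weight exponent


@dataclass
class RankMatrix:
    """Per-sample average ranks (genes x samples); largest expression = rank N."""

    ranks: pd.DataFrame

    @property
    def gene_ids(self) -> list[str]:
        return list(self.ranks.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.ranks.columns)


@dataclass
class ScoreMatrix:
    """Signatures x samples ssGSEA scores."""

    scores: pd.DataFrame
    normalized: bool
    alpha: float

    @property
    def signature_names(self) -> list[str]:
        return list(self.scores.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.columns)


def rank_transform(expr: ExpressionMatrix) -> RankMatrix:
    """Rank each sample's expression values (1..N, average ranks at ties)."""
    values = expr.data.to_numpy(dtype=float)
    ranks = rankdata(values, method="average", axis=0)
    return RankMatrix(pd.DataFrame(ranks, index=expr.data.index, columns=expr.data.columns))


def _decreasing_rank_order(ranks: np.ndarray, symbol_order: np.ndarray) -> np.ndarray:
    """Gene order indices by decreasing rank, ties by ascending symbol.

    ``symbol_order[i]`` is the alphabetical position of gene i; ``ranks`` is a
    (genes x samples) array. Returns (genes x samples) index array.
    """
    n_genes, n_samples = ranks.shape
    order = np.empty((n_genes, n_samples), dtype=np.intp)
    for j in range(n_samples):
        order[:, j] = np.lexsort((symbol_order, -ranks[:, j]))
    return order


def _es_for_set(
    weighted: np.ndarray, in_set: np.ndarray, order: np.ndarray
) -> np.ndarray:
    """Enrichment score per sample for one gene set.

    weighted: (genes x samples) rank^alpha; in_set: boolean (genes,);
    order: (genes x samples) walk order.
    """
    n_genes, n_samples = weighted.shape
    m = int(in_set.sum())
    in_ordered = in_set[order]  # (genes x samples) boolean
    w_ordered = np.take_along_axis(weighted, order, axis=0) * in_ordered
    p_in = np.cumsum(w_ordered, axis=0)
    denom = p_in[-1, :]
    p_in = p_in / denom
    p_out = np.cumsum(~in_ordered, axis=0) / (n_genes - m)
    return (p_in - p_out).sum(axis=0)


def enrichment_score(
    sample_ranks: pd.Series, gene_set: GeneSet, alpha: float = DEFAULT_ALPHA
) -> float:
    """ssGSEA enrichment score of one gene set in one sample.

    ``sample_ranks`` maps gene symbol -> rank (as produced by
    :func:`rank_transform` for one sample). Genes of the set absent from the
    ranking are dropped with a warning; a set covering all genes is an error
    because the out-of-set step function is then undefined.
    """
    genes = pd.Index(sample_ranks.index)
    members = gene_set.genes & set(genes)
    if not members:
        raise ValidationError(f"gene set {gene_set.name!r} has no overlap with the matrix")
    if len(members) < len(gene_set):
        logger.warning(
            "gene set %s: %d/%d genes absent from matrix, dropped",
            gene_set.name, len(gene_set) - len(members), len(gene_set),
        )
    if len(members) == len(genes):
        raise ValidationError(f"gene set {gene_set.name!r} covers every gene in the matrix")
    ranks = sample_ranks.to_numpy(dtype=float)[:, None]
    symbol_order = np.argsort(np.argsort(genes.to_numpy()))
    order = _decreasing_rank_order(ranks, symbol_order)
    in_set = np.asarray(genes.isin(list(members)))
    return float(_es_for_set(ranks ** alpha, in_set, order)[0])


def score_matrix(
    expr: ExpressionMatrix,
    collection: GeneSetCollection,
    alpha: float = DEFAULT_ALPHA,
    normalize: bool = True,
) -> ScoreMatrix:
    """ssGSEA scores for every set in ``collection`` across all samples.

    With ``normalize=True`` every score is divided by (max ES - min ES) over
    the entire matrix (a no-op when all scores are equal), the cohort-level
    rescaling that puts scores of different signatures on one scale.
    """
    genes = expr.data.index
    gene_set_names = set(genes)
    no_overlap = [s.name for s in collection if not (s.genes & gene_set_names)]
    if no_overlap:
        raise ValidationError(f"gene sets with no overlap with the matrix: {no_overlap[:10]}")
    full_cover = [s.name for s in collection if gene_set_names <= s.genes]
    if full_cover:
        raise ValidationError(f"gene sets covering every matrix gene: {full_cover[:10]}")

    ranks = rank_transform(expr).ranks.to_numpy(dtype=float)
    symbol_order = np.argsort(np.argsort(genes.to_numpy()))
    order = _decreasing_rank_order(ranks, symbol_order)
    weighted = ranks ** alpha

    rows = np.empty((len(collection), expr.n_samples))
    for i, s in enumerate(collection):
        members = s.genes & gene_set_names
        if len(members) < len(s):
            logger.warning(
                "gene set %s: %d/%d genes absent from matrix, dropped",
                s.name, len(s) - len(members), len(s),
            )
        in_set = np.asarray(genes.isin(list(members)))
        rows[i] = _es_for_set(weighted, in_set, order)

    if normalize:
        span = rows.max() - rows.min()
        if span > 0:
            rows = rows / span
    frame = pd.DataFrame(rows, index=collection.names, columns=expr.data.columns)
    return ScoreMatrix(frame, normalized=normalize, alpha=alpha)


def write_scores(scores: ScoreMatrix, path) -> None:
    scores.scores.to_csv(path, sep="\t", index_label="signature")
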