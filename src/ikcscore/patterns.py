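"""K-means gene-pattern discovery and immune/keratin pattern labeling.

Selected genes are standardized to z-scores across samples (so K-means
distances are scale-free) and clustered with Lloyd's algorithm (k-means++
initialization, best of ``n_init`` restarts). Clusters are then labeled by
their response association: the mean, over member genes, of (mean z in
responders - mean z in non-responders). The cluster with the largest
association is the immune pattern, the smallest the keratin pattern — the two
directions of association that the downstream composite score exploits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .core_io import ClinicalTable, ExpressionMatrix, GeneSet, ValidationError

logger = logging.getLogger("ikcscore")

#: Below this |association| the labeling is flagged as likely noise-driven.
FLAT_ASSOCIATION_WARNING = 0.1


@dataclass
class PatternAssignment:
    """Gene -> cluster assignment with immune/keratin labels.

    ``clusters`` maps gene symbol to cluster index 0..k-1; ``association``
    maps cluster index to its response-association score; ``immune`` /
    ``keratin`` are the labeled cluster indices (argmax / argmin).
    """

    clusters: pd.Series
    association: dict[int, float]
    immune: int
    keratin: int

    @property
    def immune_genes(self) -> GeneSet:
        genes = self.clusters.index[self.clusters == self.immune]
        return GeneSet("IMMUNE", "immune pattern (response-associated cluster)", frozenset(genes))

    @property
    def keratin_genes(self) -> GeneSet:
        genes = self.clusters.index[self.clusters == self.keratin]
        return GeneSet("KERATIN", "keratin pattern (non-response-associated cluster)", frozenset(genes))

    def cluster_sizes(self) -> dict[int, int]:
        return self.clusters.value_counts().sort_index().to_dict()

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"cluster": self.clusters})
        out["association"] = out["cluster"].map(self.association)
        label = {self.immune: "immune", self.keratin: "keratin"}
        out["label"] = out["cluster"].map(lambda c: label.get(c, ""))
        return out


def standardize_genes(
    expr: ExpressionMatrix, genes: Sequence[str], log2: bool = True
) -> pd.DataFrame:
    """Per-gene z-scores across samples (sample sd, ddof=1).

    With ``log2=True`` (the default for count-derived data) expression is
    transformed as log2(x + 1) before standardization, so multiplicative
    count noise does not dominate the z-scale. Genes absent from the matrix or
    constant across samples are dropped with a warning; an error is raised if
    nothing remains.
    """
    genes = list(dict.fromkeys(g.upper() for g in genes))
    present = [g for g in genes if g in set(expr.gene_ids)]
    if len(present) < len(genes):
        logger.warning("%d genes absent from matrix, dropped", len(genes) - len(present))
    if not present:
        raise ValidationError("no genes to standardize")
    values = expr.data.loc[present]
    if log2:
        values = np.log2(values + 1.0)
    sd = values.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        logger.warning("dropping %d constant genes before clustering", int(constant.sum()))
        values, sd = values[~constant], sd[~constant]
    if values.empty:
        raise ValidationError("all genes constant across samples; nothing to cluster")
    return values.sub(values.mean(axis=1), axis=0).div(sd, axis=0)


def kmeans_cluster(
    z_matrix: pd.DataFrame, k: int = 5, n_init: int = 25, seed: int | None = 0
) -> pd.Series:
    """Cluster gene z-score profiles into ``k`` patterns.

    Lloyd's algorithm with Euclidean distance, k-means++ initialization, best
    of ``n_init`` restarts by within-cluster sum of squares; deterministic
    given ``seed``.
    """
    if z_matrix.shape[0] < k:
        raise ValidationError(f"{z_matrix.shape[0]} genes < k={k} clusters")
    km = KMeans(n_clusters=k, n_init=n_init, init="k-means++",
                algorithm="lloyd", random_state=seed)
    labels = km.fit_predict(z_matrix.to_numpy(dtype=float))
    return pd.Series(labels, index=z_matrix.index, name="cluster")


def label_patterns(
    clusters: pd.Series,
    z_matrix: pd.DataFrame,
    clinical: ClinicalTable,
    tie_tol: float = 1e-12,
) -> PatternAssignment:
    """Label the immune (argmax association) and keratin (argmin) patterns.

    The association of a cluster is the mean over its genes of
    (mean z in R samples - mean z in NR samples). An exact tie at the top or
    bottom is an error (rerun with another seed or k rather than silently
    picking); near-zero associations everywhere trigger a warning.
    """
    k = clusters.nunique()
    if k < 2:
        raise ValidationError("labeling needs >= 2 clusters")
    r_ids, nr_ids = clinical.response_groups()
    r_ids = [s for s in r_ids if s in z_matrix.columns]
    nr_ids = [s for s in nr_ids if s in z_matrix.columns]
    if not r_ids or not nr_ids:
        raise ValidationError("both response groups must be present to label patterns")
    gene_assoc = z_matrix[r_ids].mean(axis=1) - z_matrix[nr_ids].mean(axis=1)
    association = {
        int(c): float(gene_assoc[clusters.index[clusters == c]].mean())
        for c in sorted(clusters.unique())
    }
    values = sorted(association.values())
    if values[-1] - values[-2] <= tie_tol or values[1] - values[0] <= tie_tol:
        raise ValidationError(
            "tied cluster associations; rerun clustering with a different seed or k"
        )
    immune = max(association, key=lambda c: association[c])
    keratin = min(association, key=lambda c: association[c])
    if max(abs(v) for v in association.values()) < FLAT_ASSOCIATION_WARNING:
        logger.warning(
            "all cluster associations below %.2g; pattern labels may be noise",
            FLAT_ASSOCIATION_WARNING,
        )
    return PatternAssignment(clusters, association, immune, keratin)
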