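"""Response-association screening: signature screen, gene screen, differential
expression, and pseudogene filtering.

All association tests are two-sided Wilcoxon rank-sum (Mann-Whitney U) tests of
responders vs non-responders, with Benjamini-Hochberg adjusted p-values reported
alongside. Raw p-values drive every "top k per direction" ranking; ties in p are
broken by decreasing |effect| and then by feature name so selections are
deterministic.

The differential-expression stage operates on median-of-ratios normalized
counts with a pseudocount log2 fold change, log2((mean_R + 1) / (mean_NR + 1)),
and the same rank-sum test per gene; candidate genes must clear both the
p-value and the |log2FC| threshold before the top-k cut.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .core_io import ClinicalTable, ExpressionMatrix, ValidationError
from .ssgsea import ScoreMatrix

logger = logging.getLogger("ikcscore")

UP_IN_R = "up_in_R"
UP_IN_NR = "up_in_NR"


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (U statistic of x, p).

    Uses the exact permutation null when both groups have <=8 observations and
    there are no ties, otherwise the normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("rank-sum test requires non-empty groups")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size <= 8 and y.size <= 8 and no_ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ScreenResult:
    """Outcome of a response-association screen.

    ``table`` holds every tested feature (columns: feature, statistic, p,
    adj_p, direction, effect); ``selected`` is the subset surviving the
    p-threshold and top-k-per-direction rule, ordered up_in_R first then
    up_in_NR, each by ascending p.
    """

    table: pd.DataFrame
    selected: pd.DataFrame

    @property
    def selected_features(self) -> list[str]:
        return list(self.selected["feature"])

    def selected_by_direction(self, direction: str) -> list[str]:
        return list(self.selected.loc[self.selected["direction"] == direction, "feature"])


def _screen_frame(values: pd.DataFrame, r_ids: list[str], nr_ids: list[str]) -> pd.DataFrame:
    """Rank-sum screen of every row of ``values`` (features x samples)."""
    records = []
    xr = values[r_ids].to_numpy(dtype=float)
    xnr = values[nr_ids].to_numpy(dtype=float)
    for i, feature in enumerate(values.index):
        stat, p = rank_sum_test(xr[i], xnr[i])
        effect = float(np.median(xr[i]) - np.median(xnr[i]))
        records.append((feature, stat, p, effect))
    table = pd.DataFrame(records, columns=["feature", "statistic", "p", "effect"])
    table["adj_p"] = bh_adjust(table["p"].to_numpy())
    table["direction"] = np.where(table["effect"] > 0, UP_IN_R, UP_IN_NR)
    return table[["feature", "statistic", "p", "adj_p", "direction", "effect"]]


def _select_top(table: pd.DataFrame, top_k: int | None, p_max: float) -> pd.DataFrame:
    passing = table[table["p"] < p_max].copy()
    passing["abs_effect"] = passing["effect"].abs()
    parts = []
    for direction in (UP_IN_R, UP_IN_NR):
        block = passing[passing["direction"] == direction]
        block = block.sort_values(
            ["p", "abs_effect", "feature"], ascending=[True, False, True]
        )
        if top_k is not None:
            block = block.head(top_k)
        parts.append(block)
    out = pd.concat(parts).drop(columns="abs_effect").reset_index(drop=True)
    if out.empty:
        logger.warning("screen selected no features at p < %g", p_max)
    return out


def _response_groups(clinical: ClinicalTable, sample_ids: Sequence[str], min_per_group: int = 2):
    r_ids, nr_ids = clinical.response_groups()
    r_ids = [s for s in r_ids if s in set(sample_ids)]
    nr_ids = [s for s in nr_ids if s in set(sample_ids)]
    if len(r_ids) < min_per_group or len(nr_ids) < min_per_group:
        raise ValidationError(
            f"need >= {min_per_group} samples per response group, got R={len(r_ids)}, NR={len(nr_ids)}"
        )
    return r_ids, nr_ids


def screen_signatures(
    scores: ScoreMatrix,
    clinical: ClinicalTable,
    top_k: int | None = 15,
    p_max: float = 0.05,
) -> ScreenResult:
    """Select the top signatures associated with response, per direction.

    Signatures with rank-sum p < ``p_max`` are ranked by ascending p within
    each direction (up in responders / up in non-responders) and at most
    ``top_k`` per direction are kept.
    """
    r_ids, nr_ids = _response_groups(clinical, scores.sample_ids)
    table = _screen_frame(scores.scores, r_ids, nr_ids)
    return ScreenResult(table, _select_top(table, top_k, p_max))


def pool_signature_genes(selected_names: Sequence[str], collection) -> list[str]:
    """Union of member genes of the selected signatures, deduplicated, sorted."""
    missing = [n for n in selected_names if n not in collection]
    if missing:
        raise ValidationError(f"selected signatures not in collection: {missing[:5]}")
    pooled: set[str] = set()
    for name in selected_names:
        pooled |= collection[name].genes
    return sorted(pooled)


def screen_gene_candidates(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    genes: Sequence[str],
    top_k: int | None = None,
    p_max: float = 0.05,
) -> ScreenResult:
    """Per-gene rank-sum screen restricted to ``genes``.

    With ``top_k=None`` all genes with p < ``p_max`` are kept; otherwise the
    top ``top_k`` per direction. Candidate genes absent from the matrix are
    dropped with a warning.
    """
    present = [g for g in dict.fromkeys(g.upper() for g in genes) if g in set(expr.gene_ids)]
    n_missing = len(set(g.upper() for g in genes)) - len(present)
    if not present:
        raise ValidationError("none of the candidate genes are in the expression matrix")
    if n_missing:
        logger.warning("%d candidate genes absent from matrix, dropped", n_missing)
    r_ids, nr_ids = _response_groups(clinical, expr.sample_ids)
    table = _screen_frame(expr.data.loc[present], r_ids, nr_ids)
    return ScreenResult(table, _select_top(table, top_k, p_max))


def normalize_counts(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Median-of-ratios (size factor) normalization of a counts matrix.

    The size factor of a sample is the median, over genes with a nonzero
    geometric mean, of count / geometric-mean; columns are divided by their
    size factors.
    """
    if counts.value_kind != "counts":
        raise ValidationError("normalize_counts expects a counts matrix")
    values = counts.data.to_numpy(dtype=float)
    if (values.sum(axis=0) == 0).any():
        bad = [s for s, tot in zip(counts.sample_ids, values.sum(axis=0)) if tot == 0]
        raise ValidationError(f"samples with all-zero counts: {bad[:5]}")
    positive = (values > 0).all(axis=1)
    if not positive.any():
        raise ValidationError("no gene has a nonzero geometric mean; cannot derive size factors")
    ref = values[positive]
    log_gm = np.mean(np.log(ref), axis=1, keepdims=True)
    ratios = ref / np.exp(log_gm)
    size_factors = np.median(ratios, axis=0)
    normalized = counts.data / size_factors
    return ExpressionMatrix(normalized, "normalized")


def differential_expression(
    counts: ExpressionMatrix,
    clinical: ClinicalTable,
    top_k: int | None = 35,
    p_max: float = 0.005,
    lfc_min: float = 1.0,
) -> ScreenResult:
    """Differential expression of responders vs non-responders.

    On median-of-ratios normalized counts: per-gene rank-sum p, pseudocount
    log2 fold change log2((mean_R + 1)/(mean_NR + 1)) reported in the
    ``effect`` column. Candidates must satisfy p < ``p_max`` and
    |log2FC| > ``lfc_min``; the top ``top_k`` per direction (by ascending p)
    are selected.
    """
    r_ids, nr_ids = _response_groups(clinical, counts.sample_ids, min_per_group=3)
    normalized = normalize_counts(counts)
    values = normalized.data
    mean_r = values[r_ids].mean(axis=1)
    mean_nr = values[nr_ids].mean(axis=1)
    lfc = np.log2((mean_r + 1.0) / (mean_nr + 1.0))

    table = _screen_frame(values, r_ids, nr_ids)
    table["effect"] = lfc.loc[table["feature"]].to_numpy()
    table["direction"] = np.where(table["effect"] > 0, UP_IN_R, UP_IN_NR)
    candidates = table[table["effect"].abs() > lfc_min]
    return ScreenResult(table, _select_top(candidates, top_k, p_max))


def filter_pseudogenes(
    genes: Sequence[str], biotype_table: Mapping[str, str] | None
) -> list[str]:
    """Drop genes whose biotype contains "pseudogene"; order preserved.

    ``biotype_table`` maps symbol -> biotype string (e.g. GENCODE-derived);
    genes absent from the table are kept. An empty/missing table passes all
    genes through with a warning.
    """
    genes = list(genes)
    if not biotype_table:
        logger.warning("no biotype table supplied; pseudogene filter is a no-op")
        return genes
    table = {k.upper(): str(v) for k, v in biotype_table.items()}
    kept = [g for g in genes if "pseudogene" not in table.get(g.upper(), "")]
    if not kept:
        logger.warning("pseudogene filter removed every gene")
    return kept


def read_biotype_table(path) -> dict[str, str]:
    """Read a two-column TSV mapping gene symbol -> biotype."""
    frame = pd.read_csv(path, sep="\t", dtype=str, comment="#", header=None)
    if frame.shape[1] != 2 or frame.isna().any().any():
        raise ValidationError(f"malformed biotype table {path}: expected 2 columns")
    return {str(k).upper(): str(v) for k, v in zip(frame[0], frame[1])}
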