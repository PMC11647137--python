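"""Data model and file I/O: expression matrices, GMT gene sets, clinical tables.

All gene symbols are upper-cased at ingestion and matching downstream is exact
string equality (after optional alias mapping), so cross-platform case or alias
ambiguity never propagates into the pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("ikcscore")

RESPONSE_CLASSES = ("CR", "PR", "SD", "PD", "NA")
#: RECIST responder mapping: complete/partial response -> R, stable/progressive
#: disease -> NR; missing response stays missing.
RESPONDER_MAP = {"CR": "R", "PR": "R", "SD": "NR", "PD": "NR", "NA": None}

CLINICAL_OPTIONAL_COLUMNS = ("pfs_time", "pfs_event", "pdl1_tps", "tmb", "tumor_purity")


class IkcError(Exception):
    """Base class for all package errors."""


class ParseError(IkcError):
    """A file could not be parsed (malformed cell, line or header)."""


class ValidationError(IkcError):
    """Parsed data violates a domain invariant."""


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric matrix with a declared value kind.

    Parameters
    ----------
    data
        DataFrame indexed by upper-case gene symbol, columns = sample ids.
    value_kind
        ``"counts"`` (non-negative integers/floats from read counting) or
        ``"normalized"`` (library-size corrected or otherwise continuous).
    """

    data: pd.DataFrame
    value_kind: str

    def __post_init__(self) -> None:
        if self.value_kind not in ("counts", "normalized"):
            raise ValidationError(f"unknown value_kind {self.value_kind!r}")
        if self.data.shape[0] < 2 or self.data.shape[1] < 2:
            raise ValidationError(
                f"expression matrix needs >=2 genes and >=2 samples, got {self.data.shape}"
            )
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids after loading: {dups[:5]}")
        if self.data.columns.has_duplicates:
            raise ValidationError("duplicate sample ids")
        values = self.data.to_numpy()
        if not np.isfinite(values).all():
            raise ValidationError("expression matrix contains non-finite values")
        if self.value_kind == "counts" and (values < 0).any():
            raise ValidationError("negative values in a counts matrix")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def read_expression(path: str | Path, value_kind: str, transpose: bool = False) -> ExpressionMatrix:
    """Read a genes-in-rows TSV expression matrix.

    The first column holds gene symbols, the header row sample ids. Symbols are
    upper-cased; duplicate gene rows are collapsed to their per-sample mean
    (logged). ``transpose=True`` handles the samples-in-rows dialect.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, index_col=0)
    if transpose:
        raw = raw.T
    raw.index = raw.index.astype(str).str.upper()
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        gene = bad.index[bad.any(axis=1)][0]
        sample = bad.columns[bad.loc[gene]][0]
        raise ParseError(
            f"non-numeric cell {raw.loc[gene, sample]!r} at gene {gene!r}, sample {sample!r} in {path}"
        )
    if numeric.shape[1] < 2:
        raise ValidationError(f"expression matrix in {path} has <2 samples")
    if numeric.index.has_duplicates:
        n_dup = int(numeric.index.duplicated().sum())
        logger.info("collapsing %d duplicate gene rows by mean", n_dup)
        order = numeric.index.drop_duplicates()
        numeric = numeric.groupby(level=0, sort=False).mean().loc[order]
    numeric.index.name = "gene"
    return ExpressionMatrix(numeric, value_kind)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneSet:
    """A named set of upper-case gene symbols."""

    name: str
    description: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("gene set name must be non-empty")
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")
        object.__setattr__(self, "genes", frozenset(g.upper() for g in self.genes))

    def __len__(self) -> int:
        return len(self.genes)

    def sorted_genes(self) -> list[str]:
        return sorted(self.genes)


@dataclass
class GeneSetCollection:
    """Ordered collection of uniquely named gene sets."""

    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(names) != len(set(names)):
            dups = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate gene set names in collection: {dups[:5]}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(s.name == name for s in self.sets)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]

    def subset(self, names: Sequence[str]) -> "GeneSetCollection":
        missing = [n for n in names if n not in self]
        if missing:
            raise ValidationError(f"gene sets not in collection: {missing[:5]}")
        return GeneSetCollection([self[n] for n in names])


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (tab-separated: name, description, member genes...)."""
    sets: list[GeneSet] = []
    names: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has <3 fields")
            name, description = fields[0], fields[1]
            if name in names:
                raise ParseError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            names.add(name)
            genes = frozenset(g.upper() for g in fields[2:] if g)
            if not genes:
                raise ParseError(f"{path}:{lineno}: gene set {name!r} has no genes")
            sets.append(GeneSet(name, description, genes))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection as GMT; genes are emitted sorted for determinism."""
    if len(collection) == 0:
        raise ValidationError("refusing to write an empty gene set collection")
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.sorted_genes()]) + "\n")


# ---------------------------------------------------------------------------
# Clinical tables
# ---------------------------------------------------------------------------


@dataclass
class ClinicalTable:
    """Per-sample clinical annotations.

    ``df`` is indexed by sample id with columns ``response_class`` (CR/PR/SD/PD
    or NA), ``responder`` ("R"/"NR", derived), and the optional numeric columns
    ``pfs_time`` (months), ``pfs_event`` (0/1), ``pdl1_tps`` (percent),
    ``tmb`` (mut/Mb), ``tumor_purity`` (fraction).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.df.index.has_duplicates:
            raise ValidationError("duplicate sample ids in clinical table")
        cls = self.df["response_class"]
        bad = set(cls.dropna()) - set(RESPONSE_CLASSES)
        if bad:
            raise ValidationError(f"unknown response class tokens: {sorted(bad)}")
        expected = cls.map(RESPONDER_MAP)
        derived = self.df["responder"].where(self.df["responder"].notna(), None)
        if not expected.where(expected.notna(), None).equals(derived):
            raise ValidationError("responder column inconsistent with response_class")
        if "pfs_time" in self.df:
            if "pfs_event" not in self.df:
                raise ValidationError("pfs_time present without pfs_event")
            has_time = self.df["pfs_time"].notna()
            if (has_time & self.df["pfs_event"].isna()).any():
                raise ValidationError("pfs_time present without pfs_event for some samples")
            if (self.df.loc[has_time, "pfs_time"] <= 0).any():
                raise ValidationError("pfs_time must be > 0")
            ev = self.df.loc[has_time, "pfs_event"]
            if not ev.isin([0, 1]).all():
                raise ValidationError("pfs_event must be 0 or 1")
        for col, lo, hi in (("pdl1_tps", 0, 100), ("tmb", 0, np.inf), ("tumor_purity", 0, 1)):
            if col in self.df:
                vals = self.df[col].dropna()
                if ((vals < lo) | (vals > hi)).any():
                    raise ValidationError(f"{col} outside [{lo}, {hi}]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    def responders(self) -> pd.Series:
        """Binary responder labels ('R'/'NR'), NA-response samples dropped."""
        return self.df["responder"].dropna()

    def response_groups(self) -> tuple[list[str], list[str]]:
        """Sample ids of (responders, non-responders), excluding NA."""
        resp = self.responders()
        return list(resp.index[resp == "R"]), list(resp.index[resp == "NR"])


def make_clinical(df: pd.DataFrame) -> ClinicalTable:
    """Build a ClinicalTable from a raw frame with a ``response`` column."""
    df = df.copy()
    cls = df["response"].fillna("NA").astype(str).str.upper()
    bad = sorted(set(cls) - set(RESPONSE_CLASSES))
    if bad:
        raise ValidationError(f"unknown response token(s): {bad}")
    out = pd.DataFrame(index=df.index)
    out["response_class"] = cls.where(cls != "NA", other=pd.NA)
    out["responder"] = cls.map(RESPONDER_MAP)
    for col in CLINICAL_OPTIONAL_COLUMNS:
        if col in df:
            out[col] = pd.to_numeric(df[col], errors="coerce")
    return ClinicalTable(out)


def read_clinical(path: str | Path) -> ClinicalTable:
    """Read a clinical TSV with columns sample_id, response, and optionally
    pfs_time, pfs_event, pdl1_tps, tmb, tumor_purity (extra columns ignored)."""
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in raw.columns:
        raise ParseError(f"{path}: missing required column 'sample_id'")
    if "response" not in raw.columns:
        raise ParseError(f"{path}: missing required column 'response'")
    raw = raw.set_index("sample_id")
    raw["response"] = raw["response"].replace({"": "NA"})
    return make_clinical(raw)


def write_clinical(table: ClinicalTable, path: str | Path) -> None:
    out = table.df.copy()
    out.insert(0, "response", out.pop("response_class"))
    out.drop(columns=["responder"]).to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Gene symbol aliases
# ---------------------------------------------------------------------------


def default_alias_table() -> dict[str, str]:
    """Alias -> canonical HGNC symbol table shipped with the package."""
    with resources.files("ikcscore.data").joinpath("gene_aliases.tsv").open() as fh:
        return _parse_alias_lines(fh, "gene_aliases.tsv")


def read_alias_table(path: str | Path) -> dict[str, str]:
    with open(path) as fh:
        return _parse_alias_lines(fh, str(path))


def _parse_alias_lines(lines: Iterable[str], source: str) -> dict[str, str]:
    table: dict[str, str] = {}
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ParseError(f"{source}:{lineno}: alias line must have 2 fields")
        alias, canonical = fields[0].upper(), fields[1].upper()
        if alias in table and table[alias] != canonical:
            raise ValidationError(
                f"{source}:{lineno}: conflicting alias {alias!r} -> {table[alias]!r} vs {canonical!r}"
            )
        table[alias] = canonical
    return table


def map_gene_symbols(genes: Sequence[str], alias_table: Mapping[str, str] | None = None) -> list[str]:
    """Replace known aliases with canonical symbols, preserving order.

    Unknown symbols pass through unchanged; symbols mapped through the alias
    table are logged. Uses the shipped default table when none is given.
    """
    if alias_table is None:
        alias_table = default_alias_table()
    alias_table = {k.upper(): v.upper() for k, v in alias_table.items()}
    out = []
    for g in genes:
        gu = g.upper()
        mapped = alias_table.get(gu, gu)
        if mapped != gu:
            logger.info("gene alias %s -> %s", gu, mapped)
        out.append(mapped)
    return out
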