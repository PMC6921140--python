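"""Readers, writers and validated containers for gene-drug association tables.

The canonical on-disk format is a delimited edge list (TSV by default) with a
header row and columns ``gene``, ``drug`` and, optionally, ``labels`` (number
of pharmacogenomic labels backing the link) and ``category`` (therapeutic
area of the drug).  Long format is used because real ADME tables are sparse.

Per-gene variability scores (aggregated minor allele frequencies of
functional variants) are read from a two-column ``gene<TAB>score`` table.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GENE_COL = "gene"
DRUG_COL = "drug"
LABEL_COL = "labels"
CATEGORY_COL = "category"


class FormatError(ValueError):
    """An input table lacks required structure (missing columns etc.)."""


class ValidationError(ValueError):
    """Table contents violate a domain invariant."""


def _norm_id(value) -> str:
    return str(value).strip()


@dataclasses.dataclass(eq=False)
class AssociationMatrix:
    """Binary gene x drug incidence with optional per-link label counts.

    ``incidence[i, j] == 1`` iff gene ``i`` is implicated in the disposition
    or toxicity of drug ``j``.  ``label_counts[i, j]`` is the number of
    pharmacogenomic labels (FDA/CPIC/DPWG) backing that link; links without
    labels carry 0 and default to weight 1 in weighted analyses.

    Invariants enforced at construction: incidence entries are 0/1, label
    counts are nonnegative and only positive on existing links, identifiers
    are unique, and no gene or drug is isolated.
    """

    genes: list
    drugs: list
    incidence: np.ndarray
    label_counts: Optional[np.ndarray] = None
    drug_categories: Optional[dict] = None

    def __post_init__(self):
        self.genes = [_norm_id(g) for g in self.genes]
        self.drugs = [_norm_id(d) for d in self.drugs]
        self.incidence = np.asarray(self.incidence)
        if self.label_counts is None:
            self.label_counts = np.zeros(self.incidence.shape, dtype=np.int64)
        self.label_counts = np.asarray(self.label_counts, dtype=np.int64)
        self.validate()

    def validate(self) -> None:
        n_g, n_d = len(self.genes), len(self.drugs)
        if n_g == 0 or n_d == 0:
            raise ValidationError("matrix must contain at least one gene and one drug")
        if len(set(self.genes)) != n_g:
            raise ValidationError("duplicate gene identifiers")
        if len(set(self.drugs)) != n_d:
            raise ValidationError("duplicate drug identifiers")
        if self.incidence.shape != (n_g, n_d):
            raise ValidationError(
                f"incidence shape {self.incidence.shape} does not match "
                f"({n_g} genes, {n_d} drugs)"
            )
        if not np.isin(self.incidence, (0, 1)).all():
            raise ValidationError("incidence entries must be 0 or 1")
        self.incidence = self.incidence.astype(np.int8)
        if self.label_counts.shape != (n_g, n_d):
            raise ValidationError("label_counts shape does not match incidence")
        if (self.label_counts < 0).any():
            raise ValidationError("label_counts must be nonnegative")
        if ((self.label_counts > 0) & (self.incidence == 0)).any():
            raise ValidationError("label count assigned to a non-existing link")
        if (self.incidence.sum(axis=1) == 0).any():
            bad = [g for g, s in zip(self.genes, self.incidence.sum(axis=1)) if s == 0]
            raise ValidationError(f"isolated gene(s) with zero drug links: {bad}")
        if (self.incidence.sum(axis=0) == 0).any():
            bad = [d for d, s in zip(self.drugs, self.incidence.sum(axis=0)) if s == 0]
            raise ValidationError(f"isolated drug(s) with zero gene links: {bad}")

    # ------------------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_drugs(self) -> int:
        return len(self.drugs)

    @property
    def gene_degrees(self) -> np.ndarray:
        """Number of drugs linked to each gene."""
        return self.incidence.sum(axis=1).astype(np.int64)

    @property
    def drug_degrees(self) -> np.ndarray:
        """Number of genes linked to each drug."""
        return self.incidence.sum(axis=0).astype(np.int64)

    @property
    def n_links(self) -> int:
        return int(self.incidence.sum())

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(_norm_id(gene))
        except ValueError:
            raise KeyError(f"unknown gene: {gene!r}") from None

    def drug_index(self, drug: str) -> int:
        try:
            return self.drugs.index(_norm_id(drug))
        except ValueError:
            raise KeyError(f"unknown drug: {drug!r}") from None

    def equals(self, other: "AssociationMatrix") -> bool:
        return (
            self.genes == other.genes
            and self.drugs == other.drugs
            and np.array_equal(self.incidence, other.incidence)
            and np.array_equal(self.label_counts, other.label_counts)
            and (self.drug_categories or {}) == (other.drug_categories or {})
        )

    __eq__ = equals

    def subset(self, genes=None, drugs=None) -> "AssociationMatrix":
        """Restrict to the given genes/drugs, dropping items left isolated.

        Items that end up with zero links after the restriction are removed
        with a logged warning rather than raising, so sub-setting workflows
        compose.
        """
        gsel = self.genes if genes is None else [_norm_id(g) for g in genes]
        dsel = self.drugs if drugs is None else [_norm_id(d) for d in drugs]
        gi = [self.gene_index(g) for g in gsel]
        di = [self.drug_index(d) for d in dsel]
        inc = self.incidence[np.ix_(gi, di)]
        lab = self.label_counts[np.ix_(gi, di)]
        keep_g = inc.sum(axis=1) > 0
        keep_d = inc.sum(axis=0) > 0
        if not keep_g.all():
            dropped = [g for g, k in zip(gsel, keep_g) if not k]
            logger.warning("dropping isolated genes after subsetting: %s", dropped)
        if not keep_d.all():
            dropped = [d for d, k in zip(dsel, keep_d) if not k]
            logger.warning("dropping isolated drugs after subsetting: %s", dropped)
        drugs_kept = [d for d, k in zip(dsel, keep_d) if k]
        cats = None
        if self.drug_categories:
            cats = {d: self.drug_categories[d] for d in drugs_kept if d in self.drug_categories}
        return AssociationMatrix(
            genes=[g for g, k in zip(gsel, keep_g) if k],
            drugs=drugs_kept,
            incidence=inc[np.ix_(keep_g, keep_d)],
            label_counts=lab[np.ix_(keep_g, keep_d)],
            drug_categories=cats,
        )


@dataclasses.dataclass(eq=False)
class VariabilityTable:
    """Per-gene aggregated minor-allele-frequency score of functional variants."""

    scores: pd.Series  # index: gene id, values: nonnegative floats

    def __post_init__(self):
        s = pd.Series(self.scores, dtype=float)
        s.index = [_norm_id(g) for g in s.index]
        if s.index.duplicated().any():
            dup = sorted(set(s.index[s.index.duplicated()]))
            raise ValidationError(f"duplicate gene(s) in variability table: {dup}")
        if (s < 0).any():
            raise ValidationError("variability scores must be nonnegative")
        if s.isna().any():
            raise ValidationError("variability scores must be numeric")
        self.scores = s

    def get(self, gene: str, default: float = 0.0) -> float:
        return float(self.scores.get(_norm_id(gene), default))

    def __len__(self) -> int:
        return len(self.scores)

    def __contains__(self, gene) -> bool:
        return _norm_id(gene) in self.scores.index

    def equals(self, other: "VariabilityTable") -> bool:
        return self.scores.equals(other.scores)

    __eq__ = equals


# ----------------------------------------------------------------------
# readers / writers


def read_associations(
    path,
    sep: str = "\t",
    gene_col: str = GENE_COL,
    drug_col: str = DRUG_COL,
    label_col: str = LABEL_COL,
    category_col: str = CATEGORY_COL,
) -> AssociationMatrix:
    """Read a long-format gene-drug edge list into an :class:`AssociationMatrix`.

    Duplicate (gene, drug) rows are collapsed with label counts summed.
    Gene and drug orderings are lexicographic, so re-reading a written table
    is deterministic.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    df.columns = [str(c).strip() for c in df.columns]
    missing = [c for c in (gene_col, drug_col) if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}; found {list(df.columns)}")
    if len(df) == 0:
        raise ValidationError(f"{path}: empty association table")

    df = df.rename(columns={gene_col: GENE_COL, drug_col: DRUG_COL})
    df[GENE_COL] = df[GENE_COL].map(_norm_id)
    df[DRUG_COL] = df[DRUG_COL].map(_norm_id)
    if (df[GENE_COL] == "").any() or (df[DRUG_COL] == "").any():
        bad = df.index[(df[GENE_COL] == "") | (df[DRUG_COL] == "")].tolist()
        raise ValidationError(f"{path}: empty identifier in row(s) {bad}")

    if label_col in df.columns:
        raw = df[label_col].fillna("0")
        counts = pd.to_numeric(raw, errors="coerce")
        if counts.isna().any():
            row = int(counts.index[counts.isna()][0])
            raise ValidationError(
                f"{path}: non-numeric label count {raw.iloc[row]!r} in row {row}"
            )
        if (counts < 0).any():
            row = int(counts.index[counts < 0][0])
            raise ValidationError(f"{path}: negative label count in row {row}")
        if not np.allclose(counts, counts.round()):
            row = int(counts.index[~np.isclose(counts, counts.round())][0])
            raise ValidationError(f"{path}: non-integer label count in row {row}")
        df[LABEL_COL] = counts.round().astype(np.int64)
    else:
        df[LABEL_COL] = 0

    categories = None
    if category_col in df.columns:
        cat = df[[DRUG_COL, category_col]].dropna()
        categories = {}
        for drug, c in zip(cat[DRUG_COL], cat[category_col]):
            c = _norm_id(c)
            if drug in categories and categories[drug] != c:
                logger.warning("conflicting categories for drug %s; keeping %r", drug, categories[drug])
            else:
                categories.setdefault(drug, c)

    grouped = df.groupby([GENE_COL, DRUG_COL], sort=True)[LABEL_COL].sum()
    genes = sorted(df[GENE_COL].unique())
    drugs = sorted(df[DRUG_COL].unique())
    g_idx = {g: i for i, g in enumerate(genes)}
    d_idx = {d: j for j, d in enumerate(drugs)}
    incidence = np.zeros((len(genes), len(drugs)), dtype=np.int8)
    labels = np.zeros((len(genes), len(drugs)), dtype=np.int64)
    for (g, d), n_lab in grouped.items():
        incidence[g_idx[g], d_idx[d]] = 1
        labels[g_idx[g], d_idx[d]] = n_lab
    return AssociationMatrix(genes, drugs, incidence, labels, categories)


def write_matrix(matrix: AssociationMatrix, path, sep: str = "\t") -> None:
    """Write an edge list such that ``read_associations`` round-trips it."""
    path = Path(path)
    rows = []
    has_cat = bool(matrix.drug_categories)
    for i, g in enumerate(matrix.genes):
        for j, d in enumerate(matrix.drugs):
            if matrix.incidence[i, j]:
                row = {GENE_COL: g, DRUG_COL: d, LABEL_COL: int(matrix.label_counts[i, j])}
                if has_cat:
                    row[CATEGORY_COL] = matrix.drug_categories.get(d, "")
                rows.append(row)
    df = pd.DataFrame(rows).sort_values([GENE_COL, DRUG_COL], kind="mergesort")
    df.to_csv(path, sep=sep, index=False)


def read_variability(path, sep: str = "\t") -> VariabilityTable:
    """Read a two-column gene / score table of aggregated functional-variant MAFs."""
    path = Path(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: variability table needs two columns (gene, score)")
    genes = df.iloc[:, 0].map(_norm_id)
    scores = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    if scores.isna().any():
        row = int(scores.index[scores.isna()][0])
        raise ValidationError(f"{path}: malformed score {df.iloc[row, 1]!r} in row {row}")
    return VariabilityTable(pd.Series(scores.values, index=list(genes)))


def write_variability(table: VariabilityTable, path, sep: str = "\t") -> None:
    path = Path(path)
    df = pd.DataFrame({GENE_COL: table.scores.index, "score": table.scores.values})
    df = df.sort_values(GENE_COL, kind="mergesort")
    df.to_csv(path, sep=sep, index=False)
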