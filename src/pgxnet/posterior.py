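"""Posterior-probability (ΔP) analysis of gene-drug co-metabolism.

For every ordered pair of pharmacogenes (i, j) we compare the conditional
probability that gene i is involved in the disposition of a drug given that
gene j is involved,

    P(X_i | X_j) = |drugs(i) ∩ drugs(j)| / |drugs(j)|,

against the unconditional (marginal) probability P(X_i) = |drugs(i)| / N.
The difference

    ΔP_ij = P(X_i | X_j) − P(X_i)

measures how much knowing that gene j handles a drug shifts the odds that
gene i handles it too.  ΔP is asymmetric: rows index the *responding* gene i
and columns the *conditioning* gene j.  Probabilities are plain
maximum-likelihood proportions with no pseudocounts or shrinkage, so worked
examples on raw counts reproduce exactly.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .io import AssociationMatrix


class UndefinedConditionalError(ValueError):
    """The conditioning gene has zero drug links, so P(·|X_j) is undefined."""


@dataclasses.dataclass(eq=False)
class PosteriorResult:
    """Marginal, conditional and ΔP matrices over all gene pairs.

    Attributes
    ----------
    genes : list of str
        Gene ordering shared by all matrices.
    marginal : (n,) ndarray
        P(X_i) = drugs linked to gene i / total drugs.
    conditional : (n, n) ndarray
        ``conditional[i, j]`` = P(X_i | X_j); the diagonal is 1.
    delta : (n, n) ndarray
        ``delta[i, j]`` = ΔP_ij = conditional[i, j] − marginal[i].
    n_drugs : int
        Total drug count N.
    """

    genes: list
    marginal: np.ndarray
    conditional: np.ndarray
    delta: np.ndarray
    n_drugs: int

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(str(gene).strip())
        except ValueError:
            raise KeyError(f"unknown gene: {gene!r}") from None

    def delta_p(self, responding: str, conditioning: str) -> float:
        """ΔP for an explicit (responding, conditioning) gene pair.

        ``delta_p(a, b)`` answers: how much more likely is gene ``a`` to be
        involved in a drug's disposition given that gene ``b`` is?
        """
        i = self.gene_index(responding)
        j = self.gene_index(conditioning)
        return float(self.delta[i, j])


def marginal_probability(matrix: AssociationMatrix, gene: str) -> float:
    """Unconditional probability that ``gene`` is involved in a random drug."""
    i = matrix.gene_index(gene)
    return float(matrix.incidence[i].sum() / matrix.n_drugs)


def conditional_probability(matrix: AssociationMatrix, gene_i: str, gene_j: str) -> float:
    """P(gene_i involved | gene_j involved) = shared drugs / drugs of gene_j."""
    i = matrix.gene_index(gene_i)
    j = matrix.gene_index(gene_j)
    w_j = int(matrix.incidence[j].sum())
    if w_j == 0:
        raise UndefinedConditionalError(
            f"gene {gene_j!r} has zero drug links; conditional undefined"
        )
    c_ij = int((matrix.incidence[i] & matrix.incidence[j]).sum())
    return c_ij / w_j


def delta_p_matrix(matrix: AssociationMatrix) -> PosteriorResult:
    """Dense gene x gene ΔP analysis of an association matrix.

    Rows are the responding gene, columns the conditioning gene
    (``delta[i, j]`` = ΔP of gene i given gene j).
    """
    if matrix.n_genes < 2:
        raise ValueError("ΔP analysis needs at least 2 genes")
    inc = matrix.incidence.astype(np.float64)
    w = inc.sum(axis=1)  # drugs per gene; > 0 post-validation
    c = inc @ inc.T  # pairwise shared-drug counts; c_ii = w_i
    conditional = c / w[np.newaxis, :]
    marginal = w / matrix.n_drugs
    delta = conditional - marginal[:, np.newaxis]
    return PosteriorResult(
        genes=list(matrix.genes),
        marginal=marginal,
        conditional=conditional,
        delta=delta,
        n_drugs=matrix.n_drugs,
    )


def top_partners(result: PosteriorResult, gene: str, k: int):
    """The ``k`` genes whose involvement is most increased by ``gene``.

    Ranks the ΔP column of the conditioning gene (largest first, excluding
    the gene itself); ties are broken lexicographically by gene id.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    j = result.gene_index(gene)
    others = [i for i in range(len(result.genes)) if i != j]
    ranked = sorted(others, key=lambda i: (-result.delta[i, j], result.genes[i]))
    return [(result.genes[i], float(result.delta[i, j])) for i in ranked[:k]]


def order_heatmap(result: PosteriorResult) -> np.ndarray:
    """Gene permutation that makes metabolic-overlap blocks contiguous.

    Agglomerative clustering (Ward linkage, Euclidean distance) on the rows
    of the symmetrized ΔP matrix; the dendrogram leaf order is returned.
    Deterministic for a fixed input.
    """
    n = len(result.genes)
    if n < 2:
        raise ValueError("heatmap ordering needs at least 2 genes")
    if n == 2:
        return np.array([0, 1])
    sym = (result.delta + result.delta.T) / 2.0
    link = hierarchy.linkage(pdist(sym), method="ward")
    return np.asarray(hierarchy.leaves_list(link))
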