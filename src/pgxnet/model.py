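"""Model/Results facade over the full gene-drug network analysis.

:class:`GeneDrugNetworkModel` holds the data (association matrix, optional
per-gene variability) and the analysis mode; :meth:`~GeneDrugNetworkModel.fit`
runs posterior-probability analysis, network construction, the constrained
2D layout, clustering and the variability overlay, returning a
:class:`GeneDrugNetworkResults` with a ``summary()`` table and accessors.

Example
-------
>>> from pgxnet import GeneDrugNetworkModel, paper_scale_preset
>>> model = GeneDrugNetworkModel.from_synthetic(paper_scale_preset(seed=1))
>>> res = model.fit(seed=1)
>>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from . import layout as layout_mod
from . import network as network_mod
from . import overlay as overlay_mod
from . import posterior as posterior_mod
from .io import AssociationMatrix, VariabilityTable, read_associations, read_variability
from .network import DegenerateNetworkError
from .synthetic import SyntheticConfig, generate


class GeneDrugNetworkModel:
    """Gene-drug co-metabolism network model.

    Parameters
    ----------
    associations : AssociationMatrix
        Binary gene x drug incidence with optional label counts.
    variability : VariabilityTable, optional
        Per-gene aggregated functional-variant MAF scores; enables the
        hotspot overlay.
    mode : {'weighted', 'unweighted'}
        Whether gene-drug edges carry pharmacogenomic label counts.
    """

    def __init__(
        self,
        associations: AssociationMatrix,
        variability: Optional[VariabilityTable] = None,
        mode: str = "weighted",
    ):
        if mode not in network_mod.MODES:
            raise ValueError(f"mode must be one of {network_mod.MODES}")
        self.associations = associations
        self.variability = variability
        self.mode = mode
        self.truth = None  # populated by from_synthetic

    @classmethod
    def from_files(cls, associations_path, variability_path=None, mode="weighted", sep="\t"):
        assoc = read_associations(associations_path, sep=sep)
        var = read_variability(variability_path, sep=sep) if variability_path else None
        return cls(assoc, var, mode=mode)

    @classmethod
    def from_synthetic(cls, config: SyntheticConfig | None = None, mode="weighted"):
        """Build the model on generated data; planted truth kept on ``.truth``."""
        config = config or SyntheticConfig()
        matrix, variability, truth = generate(config)
        model = cls(matrix, variability, mode=mode)
        model.truth = truth
        return model

    def fit(
        self,
        seed: int = 42,
        max_iter: int = 1000,
        tol: float = 1e-8,
        n_starts: int = 5,
        n_clusters: Optional[int] = None,
        cluster_method: str = "kmeans",
        weight_by_degree: bool = True,
        top_k: int = 10,
    ) -> "GeneDrugNetworkResults":
        """Run the full analysis and return a results object.

        ``n_clusters=None`` selects the silhouette-optimal k in [2, 15].
        """
        post = posterior_mod.delta_p_matrix(self.associations)
        net = network_mod.build_network(self.associations, mode=self.mode)
        lay = layout_mod.layout_vos(net, seed=seed, max_iter=max_iter, tol=tol, n_starts=n_starts)
        k = n_clusters if n_clusters is not None else layout_mod.choose_k(lay, seed=seed)
        if cluster_method == "kmeans":
            clusters = layout_mod.cluster_kmeans(lay, k, seed=seed)
        elif cluster_method == "agglomerative":
            clusters = layout_mod.cluster_agglomerative(lay, k)
        else:
            raise ValueError("cluster_method must be 'kmeans' or 'agglomerative'")
        try:
            assort = network_mod.assortativity(net)
        except DegenerateNetworkError:
            assort = None
        ovl = None
        if self.variability is not None:
            ovl = overlay_mod.overlay_variability(
                lay, net, self.variability, weight_by_degree=weight_by_degree
            )
        return GeneDrugNetworkResults(
            model=self,
            posterior=post,
            network=net,
            layout=lay,
            clusters=clusters,
            assortativity=assort,
            overlay=ovl,
            top_k=top_k,
        )


@dataclasses.dataclass(eq=False)
class GeneDrugNetworkResults:
    """Fitted gene-drug network analysis: estimates, layout and rankings."""

    model: GeneDrugNetworkModel
    posterior: posterior_mod.PosteriorResult
    network: network_mod.ItemNetwork
    layout: layout_mod.Layout2D
    clusters: layout_mod.ClusterAssignment
    assortativity: Optional[float]
    overlay: Optional[overlay_mod.OverlayResult]
    top_k: int = 10

    # -- accessors -----------------------------------------------------
    def delta_p(self, responding: str, conditioning: str) -> float:
        """ΔP of ``responding`` given ``conditioning`` (roles explicit)."""
        return self.posterior.delta_p(responding, conditioning)

    def top_partners(self, gene: str, k: int = 5):
        return posterior_mod.top_partners(self.posterior, gene, k)

    def hotspots(self, top_k: Optional[int] = None):
        if self.overlay is None:
            raise ValueError("no variability table was supplied to the model")
        return overlay_mod.hotspot_report(self.overlay, top_k or self.top_k)

    def gene_layout(self) -> layout_mod.Layout2D:
        return self.layout.subset((self.layout.items["kind"] == "gene").to_numpy())

    # -- plotting ------------------------------------------------------
    def plot_heatmap(self, path=None, **kwargs):
        from . import plotting

        return plotting.plot_delta_heatmap(self.posterior, path=path, **kwargs)

    def plot_network(self, path=None, **kwargs):
        from . import plotting

        return plotting.plot_network(self.layout, self.network, clusters=self.clusters,
                                     path=path, **kwargs)

    def plot_overlay(self, path=None, **kwargs):
        from . import plotting

        if self.overlay is None:
            raise ValueError("no variability table was supplied to the model")
        return plotting.plot_overlay(self.layout, self.overlay, path=path, **kwargs)

    # -- summary -------------------------------------------------------
    def summary(self) -> str:
        """Human-readable account of the fitted analysis."""
        m = self.model.associations
        lines = []
        w = 66
        lines.append("=" * w)
        lines.append("Gene-Drug Network Analysis".center(w))
        lines.append("=" * w)
        lines.append(f"{'Genes:':<28}{m.n_genes:>10}  {'Drugs:':<14}{m.n_drugs:>10}")
        lines.append(f"{'Gene-drug links:':<28}{m.n_links:>10}  {'Mode:':<14}{self.model.mode:>10}")
        assort = "undefined" if self.assortativity is None else f"{self.assortativity:.4f}"
        lines.append(f"{'Degree assortativity:':<28}{assort:>10}")
        lines.append("-" * w)
        lay = self.layout
        lines.append(f"{'Layout objective V:':<28}{lay.objective:>10.6g}  "
                     f"{'Iterations:':<14}{lay.iterations:>10}")
        lines.append(f"{'Constraint (mean dist):':<28}{lay.constraint_value:>10.6f}  "
                     f"{'Converged:':<14}{str(lay.converged):>10}")
        lines.append(f"{'Clusters:':<28}{self.clusters.k:>10}  "
                     f"{'Method:':<14}{self.clusters.method:>10}")
        lines.append("-" * w)
        lines.append("Strongest metabolic-overlap pairs (ΔP, responding | conditioning):")
        for resp, cond, dp in self._top_pairs(5):
            lines.append(f"  ΔP({resp} | {cond}) = {dp:+.3f}")
        if self.overlay is not None:
            mode = "MAF × degree" if self.overlay.weight_by_degree else "MAF"
            lines.append("-" * w)
            lines.append(f"Top pharmacogenetic hotspot genes (score = {mode}):")
            for _, row in self.overlay.table.head(5).iterrows():
                lines.append(
                    f"  {int(row['rank']):>2}. {row['gene']:<10} score={row['score']:.4g} "
                    f"(MAF={row['maf_score']:.4g}, degree={int(row['degree'])})"
                )
        lines.append("=" * w)
        return "\n".join(lines)

    def _top_pairs(self, k: int):
        delta = self.posterior.delta
        genes = self.posterior.genes
        n = len(genes)
        idx = [(i, j) for i in range(n) for j in range(n) if i != j]
        idx.sort(key=lambda ij: (-delta[ij], genes[ij[0]], genes[ij[1]]))
        return [(genes[i], genes[j], float(delta[i, j])) for i, j in idx[:k]]
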