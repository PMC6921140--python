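"""End-to-end pipeline runner with manifest and checksums.

Executes posterior → network → layout → clustering → overlay on either a
real edge list or a synthetic preset, writing every artifact as TSV plus a
JSON manifest with SHA-256 checksums.  Identical config and seed yield
identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import layout as layout_mod
from . import network as network_mod
from . import overlay as overlay_mod
from . import posterior as posterior_mod
from .io import read_associations, read_variability, write_matrix, write_variability
from .network import DegenerateNetworkError
from .synthetic import SyntheticConfig, generate, paper_scale_preset

logger = logging.getLogger(__name__)

PRESETS = {"paper-scale", "default"}


class PipelineConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclasses.dataclass
class PipelineConfig:
    """Configuration of one pipeline run; exactly one input source.

    Either ``associations`` (path, with optional ``variability`` path) or
    ``preset`` ('paper-scale' or 'default' synthetic data) must be set.
    """

    associations: Optional[str] = None
    variability: Optional[str] = None
    preset: Optional[str] = None
    mode: str = "weighted"
    seed: int = 42
    max_iter: int = 1000
    tol: float = 1e-8
    n_starts: int = 5
    cluster_method: str = "kmeans"
    k: Optional[int] = None
    weight_by_degree: bool = True
    top_k: int = 10
    outdir: str = "pgxnet_out"

    def __post_init__(self):
        if (self.associations is None) == (self.preset is None):
            raise PipelineConfigError(
                "exactly one of 'associations' and 'preset' must be given"
            )
        if self.preset is not None and self.preset not in PRESETS:
            raise PipelineConfigError(f"unknown preset {self.preset!r}; choose from {PRESETS}")
        if self.mode not in network_mod.MODES:
            raise PipelineConfigError(f"mode must be one of {network_mod.MODES}")
        if self.cluster_method not in ("kmeans", "agglomerative"):
            raise PipelineConfigError("cluster_method must be 'kmeans' or 'agglomerative'")
        if self.max_iter < 1 or self.n_starts < 1 or self.tol <= 0 or self.top_k < 1:
            raise PipelineConfigError("numeric parameters out of range")
        if self.k is not None and self.k < 1:
            raise PipelineConfigError("k must be >= 1")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written to disk).

    On a stage failure the partial outputs of this run are removed and the
    error re-raised with the failing stage named.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"

    def _artifact(name: str) -> Path:
        p = outdir / name
        written.append(p)
        return p

    try:
        stage = "input"
        t0 = time.perf_counter()
        if config.preset is not None:
            syn = (
                paper_scale_preset(seed=config.seed)
                if config.preset == "paper-scale"
                else SyntheticConfig(seed=config.seed)
            )
            matrix, variability, _ = generate(syn)
            write_matrix(matrix, _artifact("associations.tsv"))
            write_variability(variability, _artifact("variability.tsv"))
        else:
            matrix = read_associations(config.associations)
            variability = (
                read_variability(config.variability) if config.variability else None
            )
        logger.info("stage=input items=%dx%d wall=%.2fs", matrix.n_genes, matrix.n_drugs,
                    time.perf_counter() - t0)

        stage = "posterior"
        t0 = time.perf_counter()
        post = posterior_mod.delta_p_matrix(matrix)
        pd.DataFrame(post.delta, index=post.genes, columns=post.genes).to_csv(
            _artifact("deltap.tsv"), sep="\t", float_format="%.10g"
        )
        logger.info("stage=posterior wall=%.2fs", time.perf_counter() - t0)

        stage = "network"
        t0 = time.perf_counter()
        net = network_mod.build_network(matrix, mode=config.mode)
        network_mod.write_edgelist(net, _artifact("network_edges.tsv"))
        try:
            assort = network_mod.assortativity(net)
        except DegenerateNetworkError:
            assort = None
        logger.info("stage=network assortativity=%s wall=%.2fs", assort,
                    time.perf_counter() - t0)

        stage = "layout"
        t0 = time.perf_counter()
        lay = layout_mod.layout_vos(net, seed=config.seed, max_iter=config.max_iter,
                                    tol=config.tol, n_starts=config.n_starts)
        logger.info("stage=layout objective=%.6g constraint=%.8f wall=%.2fs",
                    lay.objective, lay.constraint_value, time.perf_counter() - t0)

        stage = "clustering"
        t0 = time.perf_counter()
        k = config.k if config.k is not None else layout_mod.choose_k(lay, seed=config.seed)
        if config.cluster_method == "kmeans":
            clusters = layout_mod.cluster_kmeans(lay, k, seed=config.seed)
        else:
            clusters = layout_mod.cluster_agglomerative(lay, k)
        deg = np.concatenate([net.bipartite.sum(axis=1), net.bipartite.sum(axis=0)])
        layout_mod.write_layout(lay, _artifact("layout.tsv"), clusters=clusters, degrees=deg)
        pd.DataFrame(
            {"item": lay.items["id"], "kind": lay.items["kind"], "cluster": clusters.labels}
        ).to_csv(_artifact("clusters.tsv"), sep="\t", index=False)
        logger.info("stage=clustering k=%d wall=%.2fs", k, time.perf_counter() - t0)

        hotspot_path = None
        if variability is not None:
            stage = "overlay"
            t0 = time.perf_counter()
            ovl = overlay_mod.overlay_variability(
                lay, net, variability, weight_by_degree=config.weight_by_degree
            )
            report = overlay_mod.hotspot_report(ovl, config.top_k)
            hotspot_path = _artifact("hotspots.tsv")
            report.to_csv(hotspot_path, sep="\t", index=False, float_format="%.10g")
            logger.info("stage=overlay wall=%.2fs", time.perf_counter() - t0)

        stage = "manifest"
        manifest = {
            "pgxnet_version": __version__,
            "seed": config.seed,
            "mode": config.mode,
            "config": dataclasses.asdict(config),
            "assortativity": assort,
            "layout_objective": lay.objective,
            "layout_constraint": lay.constraint_value,
            "n_clusters": k,
            "files": {p.name: _sha256(p) for p in written},
        }
        manifest_path = outdir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        return manifest
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
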