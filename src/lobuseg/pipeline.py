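"""End-to-end pipeline: segment -> quantify -> graph, with artifacts on disk."""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .config import RunConfig
from .io import downscale, read_volume, write_volume
from .lobule_graph import build_graph, export_graph, partition_clusters, plot_graph
from .preprocess import separate_sla
from .quantify import (
    contact_surfaces,
    edges_to_frame,
    records_to_frame,
    sla_ratio,
    subunit_volumes,
    summarize,
)
from .segmentation import segment_lobules
from .types import BinaryMask, LobusegError

__all__ = ["run_pipeline"]

logger = logging.getLogger(__name__)


def run_pipeline(
    input_path,
    config: RunConfig,
    outdir,
    exclusion_path=None,
    debug_dir=None,
) -> dict:
    """Run segment -> quantify -> graph on one volume and write all artifacts.

    Writes ``labels.tif``, ``volumes.csv``, ``edges.csv``, ``graph.graphml``,
    ``summary.json`` and ``provenance.yaml`` into ``outdir``; returns the
    summary dictionary.  The pipeline is deterministic: identical input and
    config yield byte-identical CSV outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "read"
    try:
        vol = read_volume(input_path, spacing=config.spacing)
        exclusion = None
        if exclusion_path is not None:
            exc_vol = read_volume(exclusion_path, spacing=config.spacing)
            exclusion = BinaryMask(data=exc_vol.data > 0, spacing=vol.spacing)
        if tuple(config.downscale) != (1, 1, 1):
            stage = "downscale"
            vol = downscale(vol, config.downscale)
            if exclusion is not None:
                from .types import ImageVolume

                exc_ds = downscale(
                    ImageVolume(
                        data=exclusion.data.astype(np.float64),
                        spacing=exclusion.spacing,
                    ),
                    config.downscale,
                )
                exclusion = BinaryMask(data=exc_ds.data > 0.5, spacing=vol.spacing)
        total_voxels = vol.data.size
        total_volume_mm3 = total_voxels * vol.voxel_volume_um3 / 1e9

        region = None
        sla_volume_mm3 = None
        if config.use_sla:
            stage = "separate_sla"
            region, _periphery = separate_sla(vol, config.preprocess, exclusion)
            sla_volume_mm3 = region.voxel_count * vol.voxel_volume_um3 / 1e9

        stage = "segment"
        labels = segment_lobules(
            vol, config.preprocess, config.segmentation, region=region,
            debug_dir=debug_dir,
        )
        stage = "quantify"
        records = subunit_volumes(labels)
        edges = contact_surfaces(labels)
        stage = "graph"
        graph = build_graph(records, edges)
        partition = partition_clusters(graph, config.graph_weight_threshold)
    except LobusegError as exc:
        raise LobusegError(f"pipeline failed at stage '{stage}': {exc}") from exc

    write_volume(labels, outdir / "labels.tif")
    records_to_frame(records).to_csv(outdir / "volumes.csv", index=False)
    edges_to_frame(edges).to_csv(outdir / "edges.csv", index=False)
    export_graph(graph, outdir / "graph.graphml", format="graphml")
    try:
        plot_graph(graph, outdir / "graph.png", partition)
    except Exception:  # plotting is best-effort decoration
        logger.warning("graph rendering failed; continuing without graph.png")

    volumes = [r.volume_mm3 for r in records]
    stats = summarize(volumes)
    summary = {
        "n_subunits": len(records),
        "total_volume_mm3": total_volume_mm3,
        "sla_volume_mm3": sla_volume_mm3,
        "sla_ratio_percent": (
            sla_ratio(sla_volume_mm3, total_volume_mm3)
            if sla_volume_mm3 is not None
            else None
        ),
        "subunit_volume_mean_mm3": stats.mean,
        "subunit_volume_sem_mm3": stats.sem,
        "subunit_volume_min_mm3": float(np.min(volumes)),
        "subunit_volume_max_mm3": float(np.max(volumes)),
        "n_clusters": partition.n_clusters,
        "cluster_sizes": sorted(
            (len(c) for c in partition.clusters()), reverse=True
        ),
        "graph_weight_threshold": config.graph_weight_threshold,
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    provenance = {
        "tool": "lobuseg",
        "version": __version__,
        "input": str(input_path),
        "exclusion": str(exclusion_path) if exclusion_path else None,
        "config": config.to_dict(),
    }
    with open(outdir / "provenance.yaml", "w") as fh:
        yaml.safe_dump(provenance, fh, sort_keys=True)
    return summary
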