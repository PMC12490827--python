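"""End-to-end orchestration: read -> smooth -> cluster -> detect -> aggregate.

One region at a time, split into consecutive non-overlapping tiles
(default 80 bp) when wider than the tile width; each tile is processed
independently and footprints are not deduplicated across tile borders.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import aggregation, clustering, detection, io, smoothing

logger = logging.getLogger("fpcharter")


@dataclass
class RunConfig:
    """All pipeline parameters with their library defaults."""

    k: int = clustering.DEFAULT_K
    min_cluster_size: int = clustering.DEFAULT_MIN_CLUSTER_SIZE
    smooth_window: int = smoothing.DEFAULT_SMOOTH_WINDOW_BP
    threshold: float = detection.DEFAULT_THRESHOLD
    tf_min: int = detection.DEFAULT_TF_MIN_BP
    tf_max: int = detection.DEFAULT_TF_MAX_BP
    nuc_gt: int = detection.DEFAULT_NUC_GT_BP
    min_overlap: float = aggregation.DEFAULT_MIN_OVERLAP
    tile_bp: int = io.DEFAULT_TILE_BP
    min_coverage_fraction: float = 1.0
    emit_all_labels: bool = False


@dataclass
class RegionOutput:
    """Everything one region run produces."""

    records: list[io.FootprintRecord]
    assignments: pd.DataFrame  # molecule_id, tile, cluster
    profiles: pd.DataFrame  # tile, cluster, pos, mean_protection


def run_region(
    calls: str | Path | pd.DataFrame,
    region: io.GenomicInterval,
    config: RunConfig | None = None,
    motifs: Sequence[io.GenomicInterval] | None = None,
) -> RegionOutput:
    """Run the full pipeline on one region, tiling if it exceeds the tile width."""
    config = config or RunConfig()
    records: list[io.FootprintRecord] = []
    assign_rows = []
    profile_rows = []
    for tile in region.tiles(config.tile_bp):
        tile_name = f"{tile.chrom}:{tile.start}-{tile.end}"
        try:
            matrix = io.read_meth_calls(calls, tile, config.min_coverage_fraction)
        except io.EmptyRegionError as exc:
            logger.warning("skipping tile %s: %s", tile_name, exc)
            continue
        logger.info("tile %s: %d molecules retained", tile_name, matrix.n_molecules)
        if matrix.n_molecules < 2:
            clusters = clustering.ClusterResult(
                assignments=pd.Series([1] * matrix.n_molecules).to_numpy(),
                medoids=pd.Series([0]).to_numpy(),
                k_requested=config.k,
                k_final=1,
                min_cluster_size=config.min_cluster_size,
                low_coverage=True,
            )
        else:
            smoothed = smoothing.smooth_matrix(matrix, config.smooth_window)
            dist = clustering.pairwise_distances(smoothed)
            clusters = clustering.cluster_with_size_floor(
                dist, config.k, config.min_cluster_size
            )
        logger.info(
            "tile %s: k_final=%d sizes=%s%s",
            tile_name,
            clusters.k_final,
            clusters.cluster_sizes.tolist(),
            " (low coverage)" if clusters.low_coverage else "",
        )
        footprints = detection.detect_all(
            matrix, clusters, config.threshold, config.tf_min, config.tf_max, config.nuc_gt
        )
        label_counts = pd.Series([f.label for f in footprints]).value_counts().to_dict()
        logger.info("tile %s: footprints by label %s", tile_name, label_counts)
        aggregates = aggregation.aggregate_tf_footprints(
            footprints, config.min_overlap, motifs
        )
        records.extend(
            aggregation.finalize_table(
                aggregates, footprints, matrix.n_molecules, config.emit_all_labels
            )
        )
        for mol, cid in zip(matrix.molecule_ids, clusters.assignments):
            assign_rows.append({"molecule_id": mol, "tile": tile_name, "cluster": int(cid)})
        for cid in range(1, clusters.k_final + 1):
            prof = detection.cluster_profile(matrix, clusters, cid)
            for p, v in zip(prof.positions, prof.mean_protection):
                profile_rows.append(
                    {"tile": tile_name, "cluster": cid, "pos": int(p), "mean_protection": float(v)}
                )
    return RegionOutput(
        records=records,
        assignments=pd.DataFrame(assign_rows, columns=["molecule_id", "tile", "cluster"]),
        profiles=pd.DataFrame(profile_rows, columns=["tile", "cluster", "pos", "mean_protection"]),
    )


def run_many(
    calls: str | Path | pd.DataFrame,
    regions: Sequence[io.GenomicInterval],
    config: RunConfig | None = None,
    motifs: Sequence[io.GenomicInterval] | None = None,
) -> RegionOutput:
    """Run over several regions, concatenating the outputs."""
    config = config or RunConfig()
    if not isinstance(calls, pd.DataFrame):
        calls = pd.read_csv(calls, sep="\t", dtype={"molecule_id": str, "chrom": str})
    outs = [run_region(calls, r, config, motifs) for r in regions]
    return RegionOutput(
        records=[rec for o in outs for rec in o.records],
        assignments=pd.concat(
            [o.assignments for o in outs], ignore_index=True
        ) if outs else pd.DataFrame(),
        profiles=pd.concat(
            [o.profiles for o in outs], ignore_index=True
        ) if outs else pd.DataFrame(),
    )
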