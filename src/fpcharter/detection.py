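"""Per-cluster footprint detection from raw binary protection values.

For each cluster the average protection per cytosine is computed from the
RAW (unsmoothed) binary calls; cytosines whose average exceeds 50% are
footprinted, maximal consecutive runs of footprinted cytosines become
candidate footprints, and each is classified by its genomic width:

* < 5 bp          -> "noise" (artifact)
* 5–75 bp         -> "TF"
* 76–120 bp       -> "unclassified" (between the TF and nucleosome ranges)
* > 120 bp        -> "nucleosome"

A stretch not flanked by an accessible cytosine on both sides — it touches
the edge of the covered positions — is "unrecognized", since its full
width cannot be established; this overrides the width label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clustering import ClusterResult
from .io import RegionMatrix

DEFAULT_THRESHOLD = 0.5
DEFAULT_TF_MIN_BP = 5
DEFAULT_TF_MAX_BP = 75
DEFAULT_NUC_GT_BP = 120
PROFILE_COVERAGE_FLOOR = 0.5  # fraction of cluster molecules that must cover a position


@dataclass
class ClusterProfile:
    """Average protection per cytosine for one cluster.

    Only positions covered by at least half of the cluster's molecules
    enter the profile, so sparsely covered flanks cannot create phantom
    footprints.
    """

    cluster_id: int
    positions: np.ndarray  # 1-based bp, sorted
    mean_protection: np.ndarray
    n_molecules: int


@dataclass
class Footprint:
    """One contiguous protected stretch in one cluster.

    Coordinates are the first and last footprinted cytosines, 1-based
    inclusive; width = end_pos - start_pos + 1.
    """

    cluster_id: int
    chrom: str
    start_pos: int
    end_pos: int
    label: str
    n_molecules: int

    @property
    def width(self) -> int:
        return self.end_pos - self.start_pos + 1


def cluster_profile(
    matrix: RegionMatrix, clusters: ClusterResult, cluster_id: int
) -> ClusterProfile:
    """Mean raw protection per position for the molecules of one cluster."""
    members = clusters.molecules_in(cluster_id)
    if members.size == 0:
        raise ValueError(f"cluster {cluster_id} is empty")
    sub = matrix.protection[members]
    observed = ~np.isnan(sub)
    coverage = observed.sum(axis=0)
    keep = coverage >= PROFILE_COVERAGE_FLOOR * members.size
    with np.errstate(invalid="ignore"):
        means = np.nansum(sub, axis=0) / coverage
    return ClusterProfile(
        cluster_id=cluster_id,
        positions=matrix.positions[keep],
        mean_protection=means[keep],
        n_molecules=int(members.size),
    )


def call_footprinted_positions(
    profile: ClusterProfile, threshold: float = DEFAULT_THRESHOLD
) -> np.ndarray:
    """Boolean per profile position: mean protection strictly above threshold.

    The inequality is strict, so a cytosine protected in exactly half of
    the molecules is called accessible.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    return profile.mean_protection > threshold


def segment_stretches(
    profile: ClusterProfile, footprinted: np.ndarray
) -> list[tuple[int, int, tuple[bool, bool]]]:
    """Maximal runs of consecutive footprinted cytosines.

    A run breaks only at a non-footprinted cytosine; genomic gaps without
    observed cytosines do not break runs. Each run carries edge flags
    (left, right): True when the run touches the first/last profile
    position, i.e. lacks an accessible flanking cytosine on that side.
    """
    footprinted = np.asarray(footprinted, dtype=bool)
    if footprinted.shape != profile.positions.shape:
        raise ValueError("footprinted mask must align with profile positions")
    out: list[tuple[int, int, tuple[bool, bool]]] = []
    n = footprinted.size
    i = 0
    while i < n:
        if not footprinted[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and footprinted[j + 1]:
            j += 1
        edges = (i == 0, j == n - 1)
        out.append((int(profile.positions[i]), int(profile.positions[j]), edges))
        i = j + 1
    return out


def classify_footprint(
    start_pos: int,
    end_pos: int,
    edge_flags: tuple[bool, bool],
    tf_min: int = DEFAULT_TF_MIN_BP,
    tf_max: int = DEFAULT_TF_MAX_BP,
    nuc_gt: int = DEFAULT_NUC_GT_BP,
) -> str:
    """Width-based footprint label; edge stretches are always unrecognized."""
    if start_pos > end_pos:
        raise ValueError("start_pos must be <= end_pos")
    if edge_flags[0] or edge_flags[1]:
        return "unrecognized"
    width = end_pos - start_pos + 1
    if width < tf_min:
        return "noise"
    if width <= tf_max:
        return "TF"
    if width <= nuc_gt:
        return "unclassified"
    return "nucleosome"


def detect_all(
    matrix: RegionMatrix,
    clusters: ClusterResult,
    threshold: float = DEFAULT_THRESHOLD,
    tf_min: int = DEFAULT_TF_MIN_BP,
    tf_max: int = DEFAULT_TF_MAX_BP,
    nuc_gt: int = DEFAULT_NUC_GT_BP,
) -> list[Footprint]:
    """Detect and classify footprints in every cluster."""
    footprints: list[Footprint] = []
    for cid in range(1, clusters.k_final + 1):
        profile = cluster_profile(matrix, clusters, cid)
        footprinted = call_footprinted_positions(profile, threshold)
        for start, end, edges in segment_stretches(profile, footprinted):
            footprints.append(
                Footprint(
                    cluster_id=cid,
                    chrom=matrix.interval.chrom,
                    start_pos=start,
                    end_pos=end,
                    label=classify_footprint(start, end, edges, tf_min, tf_max, nuc_gt),
                    n_molecules=profile.n_molecules,
                )
            )
    return footprints
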