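"""Aggregation of TF footprints across clusters and frequency estimation.

The same protein–DNA contact often produces footprints that are partially
shifted between clusters. TF footprints are therefore merged when they
reciprocally overlap by at least 75% of each footprint's width, or when
both are assigned to the same motif annotation. Merging is transitive
(connected components of the overlap graph), so chains of shifted
footprints collapse into one aggregate. Each aggregate's molecule count
sums every contributing cluster once, and its frequency is that count
divided by the total molecules in the region — a population-level
occupancy estimate.

Nucleosome footprints are reported per cluster and not aggregated by
default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np

from .detection import Footprint
from .io import FootprintRecord, GenomicInterval

DEFAULT_MIN_OVERLAP = 0.75


@dataclass
class AggregatedFootprint:
    """A merged TF footprint with consensus coordinates and frequency."""

    chrom: str
    start_pos: int  # 1-based inclusive consensus
    end_pos: int
    label: str
    member_footprints: list[Footprint]
    n_molecules: int
    frequency: float | None = None
    motif: str | None = None

    @property
    def clusters(self) -> list[int]:
        return sorted({f.cluster_id for f in self.member_footprints})


def overlap_fraction(
    a: tuple[str, int, int], b: tuple[str, int, int]
) -> tuple[float, float]:
    """Overlap of two 1-based inclusive intervals as a fraction of each width.

    Returns (overlap / width(a), overlap / width(b)); (0, 0) on different
    chromosomes or no overlap.
    """
    chrom_a, sa, ea = a
    chrom_b, sb, eb = b
    if chrom_a != chrom_b:
        return (0.0, 0.0)
    ov = max(0, min(ea, eb) - max(sa, sb) + 1)
    return (ov / (ea - sa + 1), ov / (eb - sb + 1))


def annotate_motif(
    footprint: tuple[str, int, int], motifs: Sequence[GenomicInterval] | None
) -> str | None:
    """Motif with the largest bp overlap with the footprint, if any.

    Motifs are BED intervals (0-based half-open) converted here to 1-based
    inclusive. At least 1 bp of overlap is required; ties go to the motif
    with the lowest start, then the lexicographically smallest name.
    """
    if not motifs:
        return None
    chrom, s, e = footprint
    best: tuple[int, int, str] | None = None  # (-overlap, start, name) minimised
    for m in motifs:
        if m.chrom != chrom or m.name is None:
            continue
        ms, me = m.start + 1, m.end  # to 1-based inclusive
        ov = min(e, me) - max(s, ms) + 1
        if ov < 1:
            continue
        key = (-ov, ms, m.name)
        if best is None or key < best:
            best = key
    return best[2] if best else None


def aggregate_tf_footprints(
    footprints: Sequence[Footprint],
    min_overlap: float = DEFAULT_MIN_OVERLAP,
    motifs: Sequence[GenomicInterval] | None = None,
) -> list[AggregatedFootprint]:
    """Merge TF footprints by reciprocal overlap and shared motif.

    Footprints are nodes; an edge joins two footprints when both overlap
    fractions reach ``min_overlap`` or both carry the same motif label.
    Connected components become aggregates with molecule-count-weighted
    mean boundaries. A cluster contributing several members to one
    component is counted once.
    """
    if not (0.0 < min_overlap <= 1.0):
        raise ValueError("min_overlap must be in (0, 1]")
    tf = [f for f in footprints if f.label == "TF"]
    if not tf:
        return []
    labels = [annotate_motif((f.chrom, f.start_pos, f.end_pos), motifs) for f in tf]

    g = nx.Graph()
    g.add_nodes_from(range(len(tf)))
    for i in range(len(tf)):
        for j in range(i + 1, len(tf)):
            fa, fb = tf[i], tf[j]
            ra, rb = overlap_fraction(
                (fa.chrom, fa.start_pos, fa.end_pos), (fb.chrom, fb.start_pos, fb.end_pos)
            )
            same_motif = labels[i] is not None and labels[i] == labels[j]
            if (ra >= min_overlap and rb >= min_overlap) or same_motif:
                g.add_edge(i, j)

    aggregates: list[AggregatedFootprint] = []
    for comp in nx.connected_components(g):
        members = sorted(comp)
        fps = [tf[i] for i in members]
        # one molecule count per distinct cluster
        per_cluster = {}
        for f in fps:
            per_cluster[f.cluster_id] = f.n_molecules
        n_mol = sum(per_cluster.values())
        w = np.array([f.n_molecules for f in fps], dtype=float)
        start = int(np.floor(np.average([f.start_pos for f in fps], weights=w) + 0.5))
        end = int(np.floor(np.average([f.end_pos for f in fps], weights=w) + 0.5))
        comp_motifs = sorted({labels[i] for i in members if labels[i] is not None})
        aggregates.append(
            AggregatedFootprint(
                chrom=fps[0].chrom,
                start_pos=start,
                end_pos=end,
                label="TF",
                member_footprints=fps,
                n_molecules=n_mol,
                motif=comp_motifs[0] if comp_motifs else None,
            )
        )
    aggregates.sort(key=lambda a: (a.chrom, a.start_pos, a.end_pos))
    return aggregates


def finalize_table(
    aggregates: Sequence[AggregatedFootprint],
    per_cluster: Sequence[Footprint],
    total_molecules: int,
    emit_all_labels: bool = False,
) -> list[FootprintRecord]:
    """Assemble the output rows: aggregated TF + per-cluster nucleosomes.

    Frequencies are molecule counts over ``total_molecules``. Noise,
    unclassified and unrecognized stretches appear only with
    ``emit_all_labels``. Coordinates convert to 0-based half-open to
    match the BED companion output. Because footprints can co-occur on
    the same molecules, frequencies may sum above 1 across rows.
    """
    if total_molecules <= 0:
        raise ValueError("total_molecules must be positive")
    records: list[FootprintRecord] = []
    for a in aggregates:
        records.append(
            FootprintRecord(
                chrom=a.chrom,
                start=a.start_pos - 1,
                end=a.end_pos,
                label=a.label,
                n_molecules=a.n_molecules,
                frequency=a.n_molecules / total_molecules,
                clusters=a.clusters,
                motif=a.motif,
            )
        )
        a.frequency = a.n_molecules / total_molecules
    other = ("nucleosome",) if not emit_all_labels else (
        "nucleosome", "noise", "unclassified", "unrecognized"
    )
    for f in per_cluster:
        if f.label in other:
            records.append(
                FootprintRecord(
                    chrom=f.chrom,
                    start=f.start_pos - 1,
                    end=f.end_pos,
                    label=f.label,
                    n_molecules=f.n_molecules,
                    frequency=f.n_molecules / total_molecules,
                    clusters=[f.cluster_id],
                )
            )
    records.sort(key=lambda r: (r.chrom, r.start, r.end, r.label))
    return records
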