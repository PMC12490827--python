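"""Data model and file I/O for single-molecule footprinting (SMF) call tables.

The interchange format is a flat TSV with one row per (molecule, cytosine)
methylation call: columns ``molecule_id``, ``chrom``, ``pos`` (1-based
genomic coordinate of the cytosine) and ``methylated`` (1 = methylated by
the exogenous enzyme, i.e. accessible; 0 = unmethylated, i.e. protected).
In memory the calls for one genomic window become a :class:`RegionMatrix`,
a molecules x positions matrix of binary *protection* values
(protection = 1 - methylated), with NaN marking positions a molecule does
not cover.

Coordinate conventions: call positions and :class:`RegionMatrix` positions
are 1-based (methylation-extractor convention); :class:`GenomicInterval`
and all BED I/O are 0-based half-open. Conversions happen only at the I/O
boundary.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Recommended analysis window width (bp) for 150 bp paired-end SMF data:
#: narrow enough that most fragments span the whole window.
DEFAULT_TILE_BP = 80

CALL_COLUMNS = ("molecule_id", "chrom", "pos", "methylated")

FOOTPRINT_LABELS = ("TF", "nucleosome", "noise", "unclassified", "unrecognized", "accessible")


class FormatError(ValueError):
    """Raised when an input file does not conform to the expected format."""


class EmptyRegionError(ValueError):
    """Raised when no molecule passes the coverage filter for a region."""


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval in BED convention (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    name: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: require 0 <= start < end"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    def contains_pos(self, pos_1based: int | np.ndarray):
        """Whether a 1-based position falls inside this interval."""
        return (self.start < pos_1based) & (pos_1based <= self.end) if isinstance(
            pos_1based, np.ndarray
        ) else self.start < pos_1based <= self.end

    def tiles(self, tile_bp: int = DEFAULT_TILE_BP) -> list["GenomicInterval"]:
        """Split into consecutive non-overlapping tiles of at most ``tile_bp``."""
        if self.width <= tile_bp:
            return [self]
        out = []
        for s in range(self.start, self.end, tile_bp):
            e = min(s + tile_bp, self.end)
            name = f"{self.name}_tile{(s - self.start) // tile_bp}" if self.name else None
            out.append(GenomicInterval(self.chrom, s, e, name))
        return out


@dataclass
class RegionMatrix:
    """Sparse molecules x cytosine-positions binary protection matrix.

    ``protection[i, j]`` is 1 if molecule i is protected at ``positions[j]``,
    0 if accessible, NaN if the molecule does not cover that cytosine.
    ``positions`` are 1-based and strictly increasing; they include every
    position covered by any retained molecule, also outside ``interval``,
    so that footprints running off the window edge can be flagged.
    """

    interval: GenomicInterval
    positions: np.ndarray  # int64, 1-based, strictly increasing
    molecule_ids: list[str]
    protection: np.ndarray  # float64, entries in {0.0, 1.0, NaN}

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.protection = np.asarray(self.protection, dtype=np.float64)
        if self.protection.shape != (len(self.molecule_ids), len(self.positions)):
            raise ValueError("protection shape does not match molecule_ids x positions")
        if len(self.positions) and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        observed = ~np.isnan(self.protection)
        if len(self.molecule_ids) and not observed.any(axis=1).all():
            raise ValueError("every molecule must have at least one observed position")

    @property
    def n_molecules(self) -> int:
        return len(self.molecule_ids)

    @property
    def in_window(self) -> np.ndarray:
        """Boolean mask over positions lying inside the analysis window."""
        return (self.positions > self.interval.start) & (self.positions <= self.interval.end)


@dataclass
class FootprintRecord:
    """One output row: an aggregated or per-cluster footprint with its frequency."""

    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    label: str
    n_molecules: int
    frequency: float
    clusters: list[int] = field(default_factory=list)
    motif: str | None = None

    def __post_init__(self) -> None:
        if self.label not in FOOTPRINT_LABELS:
            raise ValueError(f"unknown footprint label {self.label!r}")
        if not (0.0 <= self.frequency <= 1.0):
            raise ValueError(f"frequency {self.frequency} outside [0, 1]")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3+ file; the 4th column, when present, becomes the name."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            chrom, start_s, end_s = fields[0], fields[1], fields[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise FormatError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            name = fields[3] if len(fields) >= 4 and fields[3] != "." else None
            intervals.append(GenomicInterval(chrom, start, end, name))
    return intervals


def read_meth_calls(
    path: str | Path | pd.DataFrame,
    region: GenomicInterval,
    min_coverage_fraction: float = 1.0,
) -> RegionMatrix:
    """Load methylation calls overlapping ``region`` into a :class:`RegionMatrix`.

    A molecule is retained if it has at least one call inside the region and
    covers at least ``min_coverage_fraction`` of the distinct cytosine
    positions observed inside the region (across all molecules in the file).
    Retained molecules carry their full extent, including positions outside
    the region. Protection values are the inverted methylated flags.

    ``path`` may also be an in-memory DataFrame with the same columns, which
    is convenient when chaining with the simulator.
    """
    if not (0.0 <= min_coverage_fraction <= 1.0):
        raise ValueError("min_coverage_fraction must be in [0, 1]")
    if isinstance(path, pd.DataFrame):
        df = path
    else:
        df = pd.read_csv(path, sep="\t", dtype={"molecule_id": str, "chrom": str})
    missing = [c for c in CALL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"call table missing required columns: {', '.join(missing)}")
    if len(df) and not df["methylated"].isin((0, 1)).all():
        raise FormatError("methylated column must be binary (0/1)")

    df = df[df["chrom"] == region.chrom]
    pos = df["pos"].to_numpy()
    in_region = (pos > region.start) & (pos <= region.end)
    region_positions = np.unique(pos[in_region])
    if region_positions.size == 0:
        raise EmptyRegionError(
            f"no calls inside region {region.chrom}:{region.start}-{region.end}"
        )

    # coverage fraction per molecule over the distinct in-region cytosines
    in_df = df.loc[in_region]
    covered = in_df.groupby("molecule_id")["pos"].nunique()
    keep = covered[covered >= min_coverage_fraction * region_positions.size].index
    if len(keep) == 0:
        raise EmptyRegionError(
            f"no molecule covers >= {min_coverage_fraction:.0%} of the "
            f"{region_positions.size} cytosines in region "
            f"{region.chrom}:{region.start}-{region.end}"
        )

    sub = df[df["molecule_id"].isin(keep)]
    molecule_ids = sorted(sub["molecule_id"].unique())
    positions = np.unique(sub["pos"].to_numpy())
    mol_index = {m: i for i, m in enumerate(molecule_ids)}
    pos_index = {p: j for j, p in enumerate(positions)}

    protection = np.full((len(molecule_ids), len(positions)), np.nan)
    rows = sub["molecule_id"].map(mol_index).to_numpy()
    cols = sub["pos"].map(pos_index).to_numpy()
    protection[rows, cols] = 1.0 - sub["methylated"].to_numpy(dtype=np.float64)

    return RegionMatrix(region, positions, list(molecule_ids), protection)


def write_footprint_table(
    records: Sequence[FootprintRecord], path: str | Path
) -> None:
    """Write footprint records as a TSV plus a companion BED6.

    The BED is written alongside with a ``.bed`` suffix; its name column is
    ``label`` or ``label:motif`` and its score is ``round(1000 * frequency)``.
    """
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["chrom", "start", "end", "label", "n_molecules", "frequency", "clusters", "motif"])
        for r in records:
            w.writerow(
                [
                    r.chrom,
                    r.start,
                    r.end,
                    r.label,
                    r.n_molecules,
                    f"{r.frequency:.6f}",
                    ",".join(str(c) for c in r.clusters),
                    r.motif if r.motif is not None else ".",
                ]
            )
    bed_path = path.with_suffix(".bed") if path.suffix else Path(str(path) + ".bed")
    with open(bed_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for r in records:
            name = f"{r.label}:{r.motif}" if r.motif else r.label
            w.writerow([r.chrom, r.start, r.end, name, round(1000 * r.frequency), "."])


def read_footprint_table(path: str | Path) -> list[FootprintRecord]:
    """Read back a footprint TSV written by :func:`write_footprint_table`."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "clusters": str, "motif": str})
    records = []
    for row in df.itertuples(index=False):
        clusters = (
            [int(c) for c in str(row.clusters).split(",")]
            if isinstance(row.clusters, str) and row.clusters
            else []
        )
        motif = None if (not isinstance(row.motif, str) or row.motif == ".") else row.motif
        records.append(
            FootprintRecord(
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                label=row.label,
                n_molecules=int(row.n_molecules),
                frequency=float(row.frequency),
                clusters=clusters,
                motif=motif,
            )
        )
    return records
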