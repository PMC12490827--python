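"""Synthetic SMF call generator with known ground truth.

Emulates the output of a methylation extractor on single-molecule
footprinting data: binary per-cytosine protection calls on a sparse
cytosine grid, a mixture of molecular occupancy patterns (accessible /
TF-bound / nucleosome-occupied), and independent per-call flip noise.
Every molecule covers the full grid. The ground truth — which pattern
each molecule was drawn from and where each pattern's protected
intervals lie — is returned alongside the calls, so each pipeline stage
can be tested against it.

All randomness is driven by the seed in :class:`SimSpec`; identical
specs produce byte-identical tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import GenomicInterval

#: Irregular grid spacing range (bp) for realistic fixtures — matches the
#: typical density of GpC/CpG cytosines in mammalian regulatory regions.
DEFAULT_SPACING_RANGE = (4, 12)


@dataclass(frozen=True)
class Pattern:
    """One molecular occupancy pattern: protected intervals on an accessible background.

    Intervals are 1-based inclusive bp and must be disjoint.
    """

    name: str
    protected_intervals: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        ivs = sorted(self.protected_intervals)
        for s, e in ivs:
            if s > e:
                raise ValueError(f"pattern {self.name}: interval ({s},{e}) has start > end")
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 <= e1:
                raise ValueError(f"pattern {self.name}: protected intervals overlap")
        object.__setattr__(self, "protected_intervals", tuple(ivs))

    def protection_at(self, positions: np.ndarray) -> np.ndarray:
        out = np.zeros(len(positions), dtype=np.float64)
        for s, e in self.protected_intervals:
            out[(positions >= s) & (positions <= e)] = 1.0
        return out


@dataclass
class SimSpec:
    """Declarative description of one synthetic dataset."""

    region: GenomicInterval
    patterns: list[Pattern]
    weights: list[float]
    n_molecules: int
    flip_noise: float = 0.0
    seed: int = 0
    cytosine_positions: list[int] | None = None  # explicit 1-based grid
    spacing_range: tuple[int, int] = DEFAULT_SPACING_RANGE

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.patterns):
            raise ValueError("weights and patterns must have the same length")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        if not (0.0 <= self.flip_noise < 0.5):
            raise ValueError("flip_noise must be in [0, 0.5)")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "region": {
                "chrom": self.region.chrom,
                "start": self.region.start,
                "end": self.region.end,
                "name": self.region.name,
            },
            "patterns": [
                {"name": p.name, "protected_intervals": [list(iv) for iv in p.protected_intervals]}
                for p in self.patterns
            ],
            "weights": self.weights,
            "n_molecules": self.n_molecules,
            "flip_noise": self.flip_noise,
            "seed": self.seed,
            "cytosine_positions": self.cytosine_positions,
            "spacing_range": list(self.spacing_range),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimSpec":
        d = json.loads(Path(path).read_text())
        return cls(
            region=GenomicInterval(**d["region"]),
            patterns=[
                Pattern(p["name"], tuple(tuple(iv) for iv in p["protected_intervals"]))
                for p in d["patterns"]
            ],
            weights=list(d["weights"]),
            n_molecules=int(d["n_molecules"]),
            flip_noise=float(d.get("flip_noise", 0.0)),
            seed=int(d.get("seed", 0)),
            cytosine_positions=d.get("cytosine_positions"),
            spacing_range=tuple(d.get("spacing_range", DEFAULT_SPACING_RANGE)),
        )


def _grid(spec: SimSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.cytosine_positions is not None:
        grid = np.asarray(sorted(spec.cytosine_positions), dtype=np.int64)
        if grid.size == 0:
            raise ValueError("cytosine_positions must be non-empty")
        return grid
    lo, hi = spec.spacing_range
    span = spec.region.end - spec.region.start
    steps = rng.integers(lo, hi + 1, size=span)  # more than enough
    positions = spec.region.start + 1 + np.concatenate(([0], np.cumsum(steps)))
    return positions[positions <= spec.region.end].astype(np.int64)


def simulate_calls(spec: SimSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw molecules from the pattern mixture and emit a call table.

    Returns ``(calls, truth)``: ``calls`` has the standard columns
    (molecule_id, chrom, pos, methylated) with methylated = 1 - protection
    after noise; ``truth`` has one row per molecule with its source
    pattern name and that pattern's protected intervals.
    """
    rng = np.random.default_rng(spec.seed)
    grid = _grid(spec, rng)
    pattern_idx = rng.choice(len(spec.patterns), size=spec.n_molecules, p=spec.weights)

    width = len(str(spec.n_molecules - 1))
    mol_ids = [f"mol_{i:0{width}d}" for i in range(spec.n_molecules)]

    base = np.stack([p.protection_at(grid) for p in spec.patterns])
    protection = base[pattern_idx]
    if spec.flip_noise > 0:
        flips = rng.random(protection.shape) < spec.flip_noise
        protection = np.where(flips, 1.0 - protection, protection)

    n, m = protection.shape
    calls = pd.DataFrame(
        {
            "molecule_id": np.repeat(mol_ids, m),
            "chrom": spec.region.chrom,
            "pos": np.tile(grid, n),
            "methylated": (1.0 - protection).astype(np.int64).ravel(),
        }
    )
    truth = pd.DataFrame(
        {
            "molecule_id": mol_ids,
            "pattern": [spec.patterns[i].name for i in pattern_idx],
            "protected_intervals": [
                ";".join(f"{s}-{e}" for s, e in spec.patterns[i].protected_intervals)
                for i in pattern_idx
            ],
        }
    )
    return calls, truth


def make_boundary_fixture(
    width: int,
    spacing: int = 1,
    n_molecules: int = 20,
    chrom: str = "chrSim",
    flank_cytosines: int = 20,
) -> tuple[pd.DataFrame, GenomicInterval]:
    """Noise-free single-pattern fixture with one protected stretch of exact width.

    Cytosines sit every ``spacing`` bp; the protected stretch's first and
    last cytosines are exactly ``width - 1`` bp apart and are flanked by
    at least 5 accessible cytosines on each side. Returns the call table
    and an interval spanning the grid, for direct use with
    :func:`fpcharter.io.read_meth_calls`.
    """
    if width < 1 or spacing < 1:
        raise ValueError("width and spacing must be >= 1")
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    if flank_cytosines < 5:
        raise ValueError("need >= 5 accessible flanking cytosines per side")
    n_protected = (width - 1) // spacing + 1
    if (n_protected - 1) * spacing != width - 1:
        raise ValueError(
            f"width {width} not representable on a {spacing} bp grid "
            f"(first/last protected cytosines must be exactly {width - 1} bp apart)"
        )
    start_pos = 1 + flank_cytosines * spacing
    grid = np.arange(
        1, start_pos + (n_protected + flank_cytosines) * spacing, spacing, dtype=np.int64
    )
    stretch = (start_pos, start_pos + width - 1)
    span_end = int(grid[-1]) + 100
    if span_end - 0 < width + 200:
        span_end = width + 200
    region = GenomicInterval(chrom, 0, span_end)
    pattern = Pattern("stretch", (stretch,))
    spec = SimSpec(
        region=region,
        patterns=[pattern],
        weights=[1.0],
        n_molecules=n_molecules,
        flip_noise=0.0,
        seed=0,
        cytosine_positions=[int(p) for p in grid],
    )
    calls, _ = simulate_calls(spec)
    return calls, region
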