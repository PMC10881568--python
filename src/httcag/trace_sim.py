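"""Synthetic capillary-electrophoresis peak profiles for CAG-repeat PCR products.

Simulation starts at the peak level (position, height) — the entry point of
fragment-analysis software exports — rather than at raw fluorescence traces.
Each germline allele contributes a main peak, geometrically decaying PCR
stutter peaks at -1..-depth repeats, and geometrically decaying somatic
expansion peaks at +1, +2, ... repeats. Peaks falling in the same repeat bin
superpose additively (so stutter of the longer allele can merge into the
shorter allele's peak). Gaussian height noise, sparse baseline noise peaks,
bp-position jitter and detector saturation complete the measurement model.

Peak tables can be emitted in ``bp`` space or, through an affine
migration-time transform, in instrument ``raw`` space alongside a
co-electrophoresed size-standard ladder for downstream recalibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

#: sample_id suffix flagging size-standard ladder rows in peak CSV files
LADDER_SUFFIX = ".ladder"

#: Minimum simulated/retained peak height; artifact cascades stop below it.
MIN_PEAK_HEIGHT = 1.0


@dataclass(frozen=True)
class SizeStandard:
    """A co-electrophoresed DNA ladder of known fragment sizes (bp)."""

    name: str
    fragment_sizes: tuple[float, ...]

    def __post_init__(self):
        sizes = tuple(float(s) for s in self.fragment_sizes)
        if len(sizes) < 4:
            raise ValueError("size standard needs >= 4 fragments")
        if any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("fragment sizes must be strictly increasing")
        object.__setattr__(self, "fragment_sizes", sizes)


#: GeneScan-500-style ladder (bp).
GENESCAN_500 = SizeStandard(
    "GeneScan-500",
    (35, 50, 75, 100, 139, 150, 160, 200, 250, 300, 340, 350, 400, 450, 490, 500),
)


@dataclass(frozen=True)
class TraceParams:
    """Measurement-model parameters for peak-profile simulation.

    Attributes
    ----------
    stutter_ratio
        Per-repeat geometric decay of minus-strand stutter peak heights
        relative to the parent allele peak; in [0, 1).
    stutter_depth
        Maximum number of stutter positions left of an allele.
    expansion_ratio
        Per-repeat geometric decay of somatic expansion peaks; in [0, 1).
    expansion_load
        Height of the +1 expansion peak relative to its allele peak (>= 0);
        0 switches somatic mosaicism off entirely.
    noise_sd
        SD of additive zero-mean Gaussian height noise (RFU).
    main_height
        Nominal height contributed by one allele copy (RFU); a homozygote's
        single peak carries twice this.
    flank_bp
        Total non-repeat amplicon length in bp (primer-set dependent).
    saturation
        Detector ceiling; heights are clipped to (0, saturation].
    baseline_rate
        Expected number (Poisson) of spurious low-level baseline peaks.
    size_jitter_bp
        SD of fragment-sizing jitter applied to sample peak positions (bp).
    raw_slope, raw_intercept
        Affine bp -> raw migration transform used when emitting raw-space
        tables (raw = slope * bp + intercept).
    """

    stutter_ratio: float = 0.30
    stutter_depth: int = 3
    expansion_ratio: float = 0.45
    expansion_load: float = 0.20
    noise_sd: float = 30.0
    main_height: float = 1000.0
    flank_bp: float = 54.0
    saturation: float = 32000.0
    baseline_rate: float = 2.0
    size_jitter_bp: float = 0.15
    raw_slope: float = 9.6
    raw_intercept: float = 2400.0

    def __post_init__(self):
        if not 0 <= self.stutter_ratio < 1:
            raise ValueError("stutter_ratio must be in [0, 1)")
        if not 0 <= self.expansion_ratio < 1:
            raise ValueError("expansion_ratio must be in [0, 1)")
        if self.expansion_load < 0:
            raise ValueError("expansion_load must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.flank_bp <= 0:
            raise ValueError("flank_bp must be > 0")
        if self.stutter_depth < 0:
            raise ValueError("stutter_depth must be >= 0")


@dataclass(frozen=True)
class PeakTable:
    """Per-sample peak list with strictly increasing positions.

    ``space`` records the coordinate system: ``raw`` (migration units),
    ``bp`` (calibrated fragment size) or ``repeat`` (integer CAG bins).
    """

    sample_id: str
    space: str
    positions: np.ndarray
    heights: np.ndarray

    def __post_init__(self):
        positions = np.asarray(self.positions, dtype=float)
        heights = np.asarray(self.heights, dtype=float)
        if self.space not in ("raw", "bp", "repeat"):
            raise ValueError(f"unknown peak space {self.space!r}")
        if positions.shape != heights.shape or positions.ndim != 1:
            raise ValueError("positions and heights must be matching 1-D arrays")
        if positions.size and np.any(np.diff(positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(heights <= 0):
            raise ValueError("heights must be positive")
        object.__setattr__(self, "positions", positions)
        object.__setattr__(self, "heights", heights)

    def __len__(self) -> int:
        return int(self.positions.size)


def repeat_to_bp(cag: int, flank_bp: float) -> float:
    """Fragment size in bp of an amplicon with ``cag`` CAG repeats."""
    if cag < 1:
        raise ValueError("CAG count must be >= 1")
    return float(flank_bp + 3 * cag)


def _artifact_profile(allele: int, height: float, params: TraceParams) -> dict[int, float]:
    """Repeat-bin heights contributed by one allele copy."""
    bins: dict[int, float] = {allele: height}
    for k in range(1, params.stutter_depth + 1):
        h = height * params.stutter_ratio**k
        r = allele - k
        if h < MIN_PEAK_HEIGHT or r < 1:
            break
        bins[r] = bins.get(r, 0.0) + h
    if params.expansion_load > 0:
        k = 1
        while True:
            h = height * params.expansion_load * params.expansion_ratio ** (k - 1)
            if h < MIN_PEAK_HEIGHT:
                break
            bins[allele + k] = bins.get(allele + k, 0.0) + h
            k += 1
    return bins


def simulate_trace(
    genotype,
    params: TraceParams = TraceParams(),
    rng: np.random.Generator | None = None,
    space: str = "bp",
) -> PeakTable:
    """Simulate a peak table for one genotype.

    ``genotype`` is any object with ``sample_id``, ``allele_a`` and
    ``allele_b`` attributes. With ``rng=None`` the trace is noiseless and
    jitter-free (the deterministic artifact skeleton). ``space`` selects
    ``bp`` or ``raw`` output coordinates.
    """
    if space not in ("bp", "raw"):
        raise ValueError("simulate_trace emits 'bp' or 'raw' space")
    bins: dict[int, float] = {}
    for allele in (int(genotype.allele_a), int(genotype.allele_b)):
        for r, h in _artifact_profile(allele, params.main_height, params).items():
            bins[r] = bins.get(r, 0.0) + h

    if rng is not None and params.baseline_rate > 0:
        lo = 3
        hi = max(int(genotype.allele_b) + 8, lo + 1)
        for _ in range(rng.poisson(params.baseline_rate)):
            r = int(rng.integers(lo, hi + 1))
            h = abs(rng.normal(0.0, params.noise_sd)) + MIN_PEAK_HEIGHT
            bins[r] = bins.get(r, 0.0) + h

    repeats = np.array(sorted(bins), dtype=int)
    heights = np.array([bins[r] for r in repeats], dtype=float)
    if rng is not None and params.noise_sd > 0:
        heights = heights + rng.normal(0.0, params.noise_sd, size=heights.size)
    heights = np.minimum(heights, params.saturation)
    keep = heights >= MIN_PEAK_HEIGHT
    repeats, heights = repeats[keep], heights[keep]

    positions = params.flank_bp + 3.0 * repeats.astype(float)
    if rng is not None and params.size_jitter_bp > 0:
        positions = positions + rng.normal(0.0, params.size_jitter_bp, positions.size)
        order = np.argsort(positions)
        positions, heights = positions[order], heights[order]
    if space == "raw":
        positions = params.raw_slope * positions + params.raw_intercept
    return PeakTable(
        sample_id=str(genotype.sample_id),
        space=space,
        positions=positions,
        heights=heights,
    )


def ladder_trace(
    sample_id: str,
    params: TraceParams = TraceParams(),
    standard: SizeStandard = GENESCAN_500,
    space: str = "raw",
    height: float = 500.0,
) -> PeakTable:
    """Size-standard ladder peaks for one lane, in bp or raw space.

    Ladder peaks are emitted noise-free: the internal standard is the sizing
    reference and its peaks are assumed confidently identified upstream.
    """
    bp = np.array(standard.fragment_sizes, dtype=float)
    positions = params.raw_slope * bp + params.raw_intercept if space == "raw" else bp
    return PeakTable(
        sample_id=f"{sample_id}{LADDER_SUFFIX}",
        space=space,
        positions=positions,
        heights=np.full(bp.size, float(height)),
    )


def write_peak_tables(
    tables: Iterable[PeakTable], path, header_comment: str | None = None
) -> None:
    """Write peak tables to CSV (sample_id, space, position, height)."""
    frames = [
        pd.DataFrame(
            {
                "sample_id": t.sample_id,
                "space": t.space,
                "position": t.positions,
                "height": t.heights,
            }
        )
        for t in tables
    ]
    out = pd.concat(frames, ignore_index=True)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        out.to_csv(fh, index=False)


def read_peak_tables(path) -> list[PeakTable]:
    """Read a peak CSV back into PeakTable objects (file row order per sample)."""
    df = pd.read_csv(path, comment="#")
    tables = []
    for sid, sub in df.groupby("sample_id", sort=False):
        spaces = sub["space"].unique()
        if len(spaces) != 1:
            raise ValueError(f"sample {sid!r} mixes peak spaces {list(spaces)}")
        tables.append(
            PeakTable(
                sample_id=str(sid),
                space=str(spaces[0]),
                positions=sub["position"].to_numpy(),
                heights=sub["height"].to_numpy(),
            )
        )
    return tables
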