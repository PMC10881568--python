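"""Fragment sizing and germline CAG allele calling from peak tables.

The calling chain is: calibrate raw migration positions to bp against the
in-lane size-standard ladder (monotone piecewise-linear interpolation),
convert bp to integer repeat units, then call the two germline alleles.
Calling anchors on the modal (highest) peak; candidate second alleles are
screened against stutter and somatic-expansion masks defined as height
fractions of the anchor peak. The assay contract this emulates is an
accuracy of +-1 CAG repeat for alleles below 45 repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trace_sim import PeakTable, SizeStandard


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class Calibration:
    """Monotone piecewise-linear raw -> bp map with linear end extrapolation."""

    raw_knots: np.ndarray
    bp_knots: np.ndarray

    def __post_init__(self):
        raw = np.asarray(self.raw_knots, dtype=float)
        bp = np.asarray(self.bp_knots, dtype=float)
        if raw.shape != bp.shape or raw.ndim != 1 or raw.size < 2:
            raise CalibrationError("need >= 2 paired knots")
        if np.any(np.diff(raw) <= 0) or np.any(np.diff(bp) <= 0):
            raise CalibrationError("knots must be strictly increasing in both axes")
        object.__setattr__(self, "raw_knots", raw)
        object.__setattr__(self, "bp_knots", bp)

    def __call__(self, raw) -> np.ndarray:
        raw = np.asarray(raw, dtype=float)
        bp = np.interp(raw, self.raw_knots, self.bp_knots)
        # np.interp clamps outside the knot range; extrapolate with end slopes
        lo_slope = (self.bp_knots[1] - self.bp_knots[0]) / (
            self.raw_knots[1] - self.raw_knots[0]
        )
        hi_slope = (self.bp_knots[-1] - self.bp_knots[-2]) / (
            self.raw_knots[-1] - self.raw_knots[-2]
        )
        below = raw < self.raw_knots[0]
        above = raw > self.raw_knots[-1]
        bp = np.where(below, self.bp_knots[0] + (raw - self.raw_knots[0]) * lo_slope, bp)
        bp = np.where(above, self.bp_knots[-1] + (raw - self.raw_knots[-1]) * hi_slope, bp)
        return bp


def calibrate(
    ladder_peaks: PeakTable,
    standard: SizeStandard,
    min_height: float = 50.0,
) -> Calibration:
    """Fit the raw -> bp calibration from the in-lane ladder.

    Ladder peaks below ``min_height`` are dropped; the surviving peaks must
    match the standard's fragments one-to-one in order.
    """
    keep = ladder_peaks.heights >= min_height
    raw = ladder_peaks.positions[keep]
    bp = np.asarray(standard.fragment_sizes, dtype=float)
    if raw.size != bp.size:
        raise CalibrationError(
            f"ladder has {raw.size} peaks above threshold but the standard "
            f"{standard.name!r} defines {bp.size} fragments"
        )
    return Calibration(raw_knots=raw, bp_knots=bp)


def bp_to_repeat(size_bp: float, flank_bp: float) -> int:
    """Convert a fragment size to an integer CAG count.

    round((bp - flank) / 3) with ties resolved to the nearest even integer
    (the documented rounding convention of this package).
    """
    if size_bp <= flank_bp:
        raise ValueError(
            f"fragment size {size_bp} bp not larger than flank {flank_bp} bp"
        )
    return int(round((size_bp - flank_bp) / 3.0))


def peaks_to_repeat_space(peaks: PeakTable, flank_bp: float) -> PeakTable:
    """Bin a bp-space peak table into integer repeat units.

    Peaks rounding into the same repeat bin are merged by height addition;
    peaks at or below the flank size (no repeat content) are discarded.
    """
    if peaks.space != "bp":
        raise ValueError("expected a bp-space peak table")
    bins: dict[int, float] = {}
    for pos, h in zip(peaks.positions, peaks.heights):
        if pos <= flank_bp:
            continue
        r = bp_to_repeat(pos, flank_bp)
        if r >= 1:
            bins[r] = bins.get(r, 0.0) + h
    repeats = sorted(bins)
    return PeakTable(
        sample_id=peaks.sample_id,
        space="repeat",
        positions=np.array(repeats, dtype=float),
        heights=np.array([bins[r] for r in repeats], dtype=float),
    )


@dataclass(frozen=True)
class CallingParams:
    """Thresholds of the allele-calling heuristic (relative to the anchor peak).

    ``stutter_cut``: peaks within ``stutter_depth`` repeats left of a called
    allele and below this height fraction are masked as stutter.
    ``expansion_cut``: peaks right of the modal allele below this fraction are
    masked as somatic-expansion mosaicism.
    ``detect_cut``: analytical detection floor; peaks below this fraction of
    the modal height are never allele candidates (baseline suppression).
    """

    stutter_cut: float = 0.5
    expansion_cut: float = 0.5
    stutter_depth: int = 3
    detect_cut: float = 0.1
    ambiguity_cut: float = 0.75  # flag near-stutter second alleles below this ratio


@dataclass(frozen=True)
class CalledGenotype:
    sample_id: str
    allele_a: int
    allele_b: int
    modal_repeat: int
    zygosity: str
    qc_flags: tuple[str, ...] = ()

    def __post_init__(self):
        if self.allele_a > self.allele_b:
            raise ValueError("allele_a must be <= allele_b")
        if self.modal_repeat not in (self.allele_a, self.allele_b):
            raise ValueError("modal repeat must equal one of the alleles")
        if self.zygosity not in ("het", "hom"):
            raise ValueError("zygosity must be 'het' or 'hom'")


def _modal_index(repeats: np.ndarray, heights: np.ndarray) -> tuple[int, bool]:
    """Index of the highest peak; ties resolve to the larger repeat."""
    top = heights.max()
    tied = np.flatnonzero(heights == top)
    return int(tied[-1]), len(tied) > 1


def call_alleles(
    peaks: PeakTable, params: CallingParams = CallingParams()
) -> CalledGenotype:
    """Call the two germline CAG alleles from a repeat-space peak table.

    The modal (highest) peak is the first allele. The second allele is the
    tallest remaining peak that survives the detection floor, the stutter
    mask and the expansion mask; if none survives the sample is reported
    homozygous (two identical alleles, flagged — single-allele dropout is
    indistinguishable from true homozygosity at the peak-table level).
    """
    if peaks.space != "repeat":
        raise ValueError("call_alleles expects a repeat-space peak table")
    if len(peaks) == 0:
        raise ValueError(f"sample {peaks.sample_id!r}: empty peak table")
    repeats = peaks.positions.astype(int)
    heights = peaks.heights

    modal_idx, tie = _modal_index(repeats, heights)
    a1, h1 = int(repeats[modal_idx]), float(heights[modal_idx])
    flags: list[str] = []
    if tie:
        flags.append("modal-height-tie")

    detectable = heights >= params.detect_cut * h1
    left = repeats < a1
    in_stutter_range = (repeats >= a1 - params.stutter_depth) & left
    stutter_masked = in_stutter_range & (heights < params.stutter_cut * h1)
    expansion_masked = (repeats > a1) & (heights < params.expansion_cut * h1)
    candidate = detectable & ~stutter_masked & ~expansion_masked
    candidate[modal_idx] = False

    # masked peaks tall enough to merit review
    for r, h, masked in zip(repeats, heights, stutter_masked | expansion_masked):
        if masked and h >= 0.35 * h1:
            flags.append(f"masked-peak:{int(r)}")

    if candidate.any():
        cand_idx = np.flatnonzero(candidate)
        best = cand_idx[np.lexsort((repeats[cand_idx], heights[cand_idx]))[-1]]
        a2, h2 = int(repeats[best]), float(heights[best])
        if in_stutter_range[best] and h2 < params.ambiguity_cut * h1:
            flags.append("adjacent-allele-ambiguity")
        zygosity = "het"
    else:
        a2 = a1
        zygosity = "hom"
        flags.append("homozygous-or-dropout")

    return CalledGenotype(
        sample_id=peaks.sample_id,
        allele_a=min(a1, a2),
        allele_b=max(a1, a2),
        modal_repeat=a1,
        zygosity=zygosity,
        qc_flags=tuple(flags),
    )


def calls_to_frame(calls) -> pd.DataFrame:
    """Tabulate CalledGenotype records (qc_flags semicolon-joined)."""
    return pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in calls],
            "allele_a": [c.allele_a for c in calls],
            "allele_b": [c.allele_b for c in calls],
            "modal_repeat": [c.modal_repeat for c in calls],
            "zygosity": [c.zygosity for c in calls],
            "qc_flags": [";".join(c.qc_flags) for c in calls],
        }
    )


def write_calls(calls, path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        calls_to_frame(calls).to_csv(fh, sep="\t", index=False)


def read_calls(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", keep_default_na=False)
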