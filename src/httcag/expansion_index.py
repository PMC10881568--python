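"""Somatic CAG repeat expansion index (EI) from fragment-analysis peak heights.

The EI quantifies somatic mosaicism as the peak-height-weighted mean repeat
distance of expansion peaks to the right of the modal allele peak. With
modal peak height h0 at repeat r0, the retained set is the modal peak plus
every peak at repeat r > r0 whose height is at least a fraction ``c``
(default 0.20) of h0; then

    EI = sum_i h_i * (r_i - r0) / sum_i h_i        over the retained set.

The modal peak contributes distance 0, so EI = 0 exactly when no expansion
peak is retained, and EI is invariant to uniform height rescaling.

For heterozygous samples the pipeline anchors the statistic on the *larger*
germline allele (see :func:`expansion_index_for_allele`): peaks are first
restricted to repeats at or above that allele so that the second germline
allele of a heterozygote is never counted as somatic expansion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trace_sim import PeakTable


@dataclass(frozen=True)
class EIResult:
    """Per-sample expansion-index computation record."""

    sample_id: str
    modal_repeat: int
    threshold: float
    retained: tuple[tuple[int, float], ...]
    ei: float
    flags: tuple[str, ...] = ()

    def __post_init__(self):
        if self.ei < 0:
            raise ValueError("EI must be non-negative")

    @property
    def n_expansion_peaks(self) -> int:
        return sum(1 for r, _ in self.retained if r > self.modal_repeat)


def compute_expansion_index(peaks: PeakTable, c: float = 0.20) -> EIResult:
    """Expansion index of a repeat-space peak table.

    The modal peak is the highest peak; a height tie resolves to the larger
    repeat (conservative: it can only reduce the index) and raises a flag.
    ``c`` is the retention threshold as a fraction of the modal height,
    0 <= c < 1.
    """
    if peaks.space != "repeat":
        raise ValueError("expansion index expects a repeat-space peak table")
    if len(peaks) == 0:
        raise ValueError(f"sample {peaks.sample_id!r}: empty peak table")
    if not 0 <= c < 1:
        raise ValueError("threshold c must be in [0, 1)")
    repeats = peaks.positions.astype(int)
    heights = peaks.heights

    top = heights.max()
    tied = np.flatnonzero(heights == top)
    modal_idx = int(tied[-1])
    flags = ("modal-height-tie",) if len(tied) > 1 else ()
    r0, h0 = int(repeats[modal_idx]), float(heights[modal_idx])

    # ratio comparison: h/h0 >= c is exact at the boundary for integer
    # heights (e.g. 200/1000 == 0.2), unlike h >= c*h0
    keep = (repeats > r0) & (heights / h0 >= c)
    retained_r = np.concatenate(([r0], repeats[keep]))
    retained_h = np.concatenate(([h0], heights[keep]))
    ei = float(np.sum(retained_h * (retained_r - r0)) / np.sum(retained_h))
    return EIResult(
        sample_id=peaks.sample_id,
        modal_repeat=r0,
        threshold=float(c),
        retained=tuple(zip(retained_r.tolist(), retained_h.tolist())),
        ei=ei,
        flags=flags,
    )


def expansion_index_for_allele(
    peaks: PeakTable, anchor_allele: int, c: float = 0.20
) -> EIResult:
    """Expansion index anchored on a known germline allele.

    Restricts the table to repeats >= ``anchor_allele`` (normally the larger
    called allele) before computing the modal-anchored index, so that in a
    heterozygote the other germline allele — which lies right of the modal
    peak whenever the shorter allele is modal — is not mistaken for somatic
    expansion. With no expansion signal the result is exactly 0.
    """
    mask = peaks.positions.astype(int) >= int(anchor_allele)
    if not mask.any():
        raise ValueError(
            f"sample {peaks.sample_id!r}: no peaks at or above anchor allele "
            f"{anchor_allele}"
        )
    sub = PeakTable(
        sample_id=peaks.sample_id,
        space="repeat",
        positions=peaks.positions[mask],
        heights=peaks.heights[mask],
    )
    return compute_expansion_index(sub, c=c)


def summarize_ei(
    results, grouping: pd.Series | dict, warn=None
) -> pd.DataFrame:
    """Arithmetic mean EI per group.

    ``grouping`` maps sample_id -> group label. Samples with no group and
    groups with no samples are dropped with a warning callback (default:
    silently omitted).
    """
    grouping = pd.Series(grouping)
    rows = {r.sample_id: r.ei for r in results}
    ei = pd.Series(rows, name="ei")
    known = ei.index.intersection(grouping.index)
    missing = ei.index.difference(grouping.index)
    if len(missing) and warn is not None:
        warn(f"{len(missing)} samples lack a group label and were omitted")
    frame = pd.DataFrame({"ei": ei.loc[known], "group": grouping.loc[known]})
    out = (
        frame.groupby("group", sort=False)["ei"]
        .agg(n="size", mean_ei="mean")
        .reset_index()
    )
    return out


def ei_results_to_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "modal_repeat": [r.modal_repeat for r in results],
            "threshold": [r.threshold for r in results],
            "n_retained_expansion_peaks": [r.n_expansion_peaks for r in results],
            "ei": [r.ei for r in results],
        }
    )
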