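"""Synthetic HTT CAG genotype cohorts with Lynch-syndrome group structure.

Generates biallelic integer CAG genotypes from a configurable population
allele-size distribution (modal size ~17 repeats, long right tail), arranged
in labelled groups (controls plus mismatch-repair gene subgroups), with an
optional per-allele mean shift and an exact number of intermediate-allele
carriers per group. A JSON-serializable ledger records the spec and the
per-group child seeds so any group can be regenerated independently.

The population allele model is a stand-in: no individual-level allele
frequencies are published for the cohorts this emulates. Its intermediate
band mass (~6-7% of alleles in 27-35) echoes reported population frequencies
of HTT intermediate alleles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort_stats import NORMAL_MAX, is_intermediate


class CohortError(ValueError):
    """Invalid cohort specification (e.g. more forced carriers than samples)."""


@dataclass(frozen=True)
class AlleleModel:
    """Discrete distribution of CAG allele sizes.

    Attributes
    ----------
    support
        Inclusive, contiguous integer range of CAG counts (ascending).
    weights
        Relative frequency per count; normalized to sum to 1 on construction.
    """

    support: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        support = np.asarray(self.support, dtype=int)
        weights = np.asarray(self.weights, dtype=float)
        if support.size == 0:
            raise CohortError("allele model has empty support")
        if support[0] < 1:
            raise CohortError("support lower bound must be >= 1")
        if np.any(np.diff(support) != 1):
            raise CohortError("support must be a contiguous ascending range")
        if weights.shape != support.shape:
            raise CohortError("weights must align with support")
        if np.any(weights < 0):
            raise CohortError("weights must be non-negative")
        total = weights.sum()
        if total <= 0:
            raise CohortError("weights must have positive total mass")
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "weights", weights / total)

    @classmethod
    def default(
        cls,
        lo: int = 9,
        hi: int = 55,
        mode: float = 17.0,
        sigma: float = 0.25,
    ) -> "AlleleModel":
        """Truncated, discretized log-normal allele-size distribution.

        Parameterized by the modal allele size (a log-normal with scale
        ``mode * exp(sigma^2)`` peaks at ``mode``). Defaults put the mode at
        17 repeats with ~6% of alleles in the intermediate band (27-35),
        mimicking population HTT allele data.
        """
        support = np.arange(lo, hi + 1)
        dist = sps.lognorm(s=sigma, scale=mode * math.exp(sigma**2))
        weights = dist.cdf(support + 0.5) - dist.cdf(support - 0.5)
        return cls(support=support, weights=weights)

    @classmethod
    def point_mass(cls, cag: int) -> "AlleleModel":
        return cls(support=np.array([cag]), weights=np.array([1.0]))

    @property
    def mean(self) -> float:
        """Analytic expectation sum(c * w(c))."""
        return float(np.sum(self.support * self.weights))

    @property
    def intermediate_prob(self) -> float:
        """Probability mass on the intermediate band 27-35."""
        return float(self.weights[is_intermediate(self.support)].sum())

    def conditioned(self, mask: np.ndarray) -> "AlleleModel":
        """Restrict to the masked support values and renormalize.

        The result keeps a contiguous support range (zero weight where the
        mask is false) so downstream invariants on contiguity hold.
        """
        mask = np.asarray(mask, dtype=bool)
        if not mask.any() or self.weights[mask].sum() <= 0:
            raise CohortError("conditioning mask removes all probability mass")
        weights = np.where(mask, self.weights, 0.0)
        return AlleleModel(support=self.support, weights=weights)

    def shifted(self, delta: float) -> "AlleleModel":
        """Shift the distribution mean by exactly ``delta`` repeats.

        Non-integer shifts are realized as a two-point mixture: the pmf moved
        by floor(delta) with probability 1-frac and by floor(delta)+1 with
        probability frac, which changes the expectation by exactly delta.
        The support range is extended to accommodate the shift.
        """
        if delta == 0:
            return self
        a = math.floor(delta)
        f = delta - a
        lo, hi = int(self.support[0]), int(self.support[-1])
        new_lo, new_hi = lo + a, hi + a + (1 if f > 0 else 0)
        if new_lo < 1:
            raise CohortError(
                f"shift {delta} pushes support lower bound below 1 CAG repeat"
            )
        support = np.arange(new_lo, new_hi + 1)
        weights = np.zeros(support.size)
        weights[: self.support.size] += (1.0 - f) * self.weights
        if f > 0:
            weights[1 : 1 + self.support.size] += f * self.weights
        return AlleleModel(support=support, weights=weights)


def sample_alleles(model: AlleleModel, size, rng: np.random.Generator) -> np.ndarray:
    """Draw integer CAG allele sizes i.i.d. from the model."""
    return rng.choice(model.support, size=size, p=model.weights)


def sample_allele(model: AlleleModel, rng: np.random.Generator) -> int:
    """Draw a single CAG allele size."""
    return int(sample_alleles(model, None, rng))


@dataclass(frozen=True)
class Genotype:
    """One individual's pair of CAG allele sizes (ordered allele_a <= allele_b)."""

    sample_id: str
    group: str
    allele_a: int
    allele_b: int

    def __post_init__(self):
        if self.allele_a > self.allele_b:
            raise CohortError("allele_a must be <= allele_b")
        if self.allele_a < 1:
            raise CohortError("allele sizes must be >= 1")


@dataclass(frozen=True)
class GroupSpec:
    """One cohort group: label, size, optional mean shift and forced carriers.

    ``forced_intermediate_carriers = None`` samples freely from the allele
    model; an integer k forces exactly k individuals to carry precisely one
    intermediate allele (27-35) while everyone else carries normal-range
    alleles (<= 26).
    """

    label: str
    n: int
    mean_shift: float = 0.0
    forced_intermediate_carriers: int | None = None
    allele_model: AlleleModel | None = None

    def __post_init__(self):
        if self.n < 1:
            raise CohortError(f"group {self.label!r}: n must be >= 1")
        k = self.forced_intermediate_carriers
        if k is not None and not 0 <= k <= self.n:
            raise CohortError(
                f"group {self.label!r}: {k} forced carriers impossible with n={self.n}"
            )


@dataclass(frozen=True)
class CohortSpec:
    groups: tuple[GroupSpec, ...]
    seed: int = 0

    def __post_init__(self):
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise CohortError("group labels must be unique")
        object.__setattr__(self, "groups", tuple(self.groups))


#: Group sizes and intermediate-carrier counts of the two study cohorts.
BOCHUM_GROUPS = (
    ("controls", 559, 29),
    ("MLH1", 60, 1),
    ("MSH2", 88, 3),
    ("MSH6", 23, 1),
)
LUND_GROUPS = (
    ("controls", 19, 1),
    ("MLH1", 12, 1),
    ("MSH2", 15, 1),
    ("MSH6", 21, 0),
)


def cohort_spec_from_counts(
    counts: Sequence[tuple[str, int, int]],
    seed: int = 0,
    allele_model: AlleleModel | None = None,
) -> CohortSpec:
    """Build a CohortSpec from (label, n, forced_carriers) triples."""
    return CohortSpec(
        groups=tuple(
            GroupSpec(
                label=label,
                n=n,
                forced_intermediate_carriers=k,
                allele_model=allele_model,
            )
            for label, n, k in counts
        ),
        seed=seed,
    )


def _sample_group(
    group: GroupSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Return (n, 2) allele array and boolean carrier-designation array."""
    model = group.allele_model or AlleleModel.default()
    if group.mean_shift:
        model = model.shifted(group.mean_shift)
    n, k = group.n, group.forced_intermediate_carriers
    if k is None:
        alleles = sample_alleles(model, (n, 2), rng)
        return alleles, is_intermediate(alleles).any(axis=1)

    inter_mask = is_intermediate(model.support)
    normal_mask = model.support <= NORMAL_MAX
    if not (model.weights[normal_mask].sum() > 0):
        # model puts no mass at <= 26: fall back to the band complement
        normal_mask = ~inter_mask
    normal_model = model.conditioned(normal_mask)
    alleles = sample_alleles(normal_model, (n, 2), rng)
    carrier = np.zeros(n, dtype=bool)
    if k > 0:
        inter_model = model.conditioned(inter_mask)
        idx = rng.choice(n, size=k, replace=False)
        side = rng.integers(0, 2, size=k)
        alleles[idx, side] = sample_alleles(inter_model, k, rng)
        carrier[idx] = True
    return alleles, carrier


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, dict]:
    """Generate a cohort genotype table and its ground-truth ledger.

    Returns
    -------
    cohort
        DataFrame with columns ``sample_id, group, allele_a, allele_b``
        (allele_a <= allele_b), exactly ``n`` rows per group, deterministic
        for a fixed ``spec.seed``.
    ledger
        JSON-serializable dict echoing the spec, the parent seed, per-group
        child seed keys and the forced-carrier sample ids.
    """
    parent = np.random.SeedSequence(spec.seed)
    children = parent.spawn(len(spec.groups))
    frames = []
    ledger_groups = []
    for group, child in zip(spec.groups, children):
        rng = np.random.default_rng(child)
        alleles, carrier = _sample_group(group, rng)
        alleles = np.sort(alleles, axis=1)
        sample_ids = [f"{group.label}-{i + 1:04d}" for i in range(group.n)]
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": sample_ids,
                    "group": group.label,
                    "allele_a": alleles[:, 0],
                    "allele_b": alleles[:, 1],
                }
            )
        )
        ledger_groups.append(
            {
                "label": group.label,
                "n": group.n,
                "mean_shift": group.mean_shift,
                "forced_intermediate_carriers": group.forced_intermediate_carriers,
                "spawn_key": [int(x) for x in child.spawn_key],
                "carrier_sample_ids": [
                    sid for sid, c in zip(sample_ids, carrier) if c
                ],
            }
        )
    cohort = pd.concat(frames, ignore_index=True)
    ledger = {"seed": int(spec.seed), "groups": ledger_groups}
    return cohort, ledger


def write_cohort(cohort: pd.DataFrame, path, header_comment: str | None = None) -> None:
    """Write the genotype table as TSV (optionally with a '#' header line)."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        cohort.to_csv(fh, sep="\t", index=False)


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
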