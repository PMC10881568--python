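"""End-to-end orchestration: simulate -> call -> expansion index -> statistics.

Stages communicate through plain-text files in an output directory so each
can be re-run independently from intermediates:

    cohort.tsv          truth genotype table (simulate-cohort)
    cohort_ledger.json  spec echo + per-group seeds
    peaks.csv           per-sample peak tables + in-lane ladders (simulate-traces)
    called.tsv          called genotypes (call)
    ei.tsv              per-sample expansion index (ei)
    table1.tsv          per-group summary table (stats)
    comparisons.tsv     pooled t-tests vs controls (stats)
    manifest.json       config echo, config hash, seed, package version

Every text output carries a '# httcag config=<hash> seed=<seed>' header line
and the whole bundle is byte-deterministic for a fixed config + seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort_stats import compare_to_controls, table_one
from .expansion_index import ei_results_to_frame, expansion_index_for_allele
from .fragment_calling import (
    CallingParams,
    calibrate,
    call_alleles,
    peaks_to_repeat_space,
    read_calls,
    write_calls,
)
from .synthetic_cohort import (
    BOCHUM_GROUPS,
    LUND_GROUPS,
    CohortSpec,
    GroupSpec,
    cohort_spec_from_counts,
    generate_cohort,
    read_cohort,
    write_cohort,
)
from .trace_sim import (
    GENESCAN_500,
    LADDER_SUFFIX,
    PeakTable,
    TraceParams,
    ladder_trace,
    read_peak_tables,
    simulate_trace,
    write_peak_tables,
)


class PipelineError(RuntimeError):
    """Stage failure, annotated with stage name and sample context."""


#: Primer-set profiles: total non-repeat amplicon length in bp. The exact
#: published amplicon offsets for the two assays are not public constants;
#: these are configurable defaults, one per named profile.
PRIMER_PROFILES = {"lund": 54.0, "bochum": 87.0}

COHORT_PRESETS = {"bochum": BOCHUM_GROUPS, "lund": LUND_GROUPS}


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration (YAML-serializable)."""

    cohort: str | tuple = "bochum"  # preset name or (label, n, carriers) triples
    primer_profile: str = "bochum"
    trace: TraceParams = field(default_factory=TraceParams)
    calling: CallingParams = field(default_factory=CallingParams)
    ei_threshold: float = 0.20
    alpha: float = 0.05
    m_comparisons: int = 3
    control_label: str = "controls"
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.cohort, str) and self.cohort not in COHORT_PRESETS:
            raise ValueError(
                f"unknown cohort preset {self.cohort!r}; "
                f"choose from {sorted(COHORT_PRESETS)} or give group triples"
            )
        if self.primer_profile not in PRIMER_PROFILES:
            raise ValueError(
                f"unknown primer profile {self.primer_profile!r}; "
                f"choose from {sorted(PRIMER_PROFILES)}"
            )
        # trace flank follows the primer profile unless explicitly overridden
        flank = PRIMER_PROFILES[self.primer_profile]
        if self.trace.flank_bp != flank:
            object.__setattr__(self, "trace", replace(self.trace, flank_bp=flank))

    @property
    def flank_bp(self) -> float:
        return PRIMER_PROFILES[self.primer_profile]

    def cohort_spec(self, seed: int | None = None) -> CohortSpec:
        counts = (
            COHORT_PRESETS[self.cohort]
            if isinstance(self.cohort, str)
            else self.cohort
        )
        return cohort_spec_from_counts(
            counts, seed=self.seed if seed is None else seed
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        if not isinstance(d["cohort"], str):
            d["cohort"] = [list(g) for g in d["cohort"]]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "trace" in d and isinstance(d["trace"], dict):
            d["trace"] = TraceParams(**d["trace"])
        if "calling" in d and isinstance(d["calling"], dict):
            d["calling"] = CallingParams(**d["calling"])
        if "cohort" in d and not isinstance(d["cohort"], str):
            d["cohort"] = tuple(tuple(g) for g in d["cohort"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def header(self) -> str:
        return f"httcag config={self.config_hash()} seed={self.seed}"


def _child_seed(seed: int, stage: str) -> np.random.SeedSequence:
    tag = int.from_bytes(hashlib.sha256(stage.encode()).digest()[:4], "big")
    return np.random.SeedSequence(entropy=seed, spawn_key=(tag,))


def simulate_cohort_stage(config: RunConfig, outdir: Path) -> pd.DataFrame:
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        cohort, ledger = generate_cohort(config.cohort_spec())
    except Exception as exc:  # noqa: BLE001 - annotate stage context
        raise PipelineError(f"stage=simulate-cohort: {exc}") from exc
    write_cohort(cohort, outdir / "cohort.tsv", header_comment=config.header())
    ledger["config_hash"] = config.config_hash()
    with open(outdir / "cohort_ledger.json", "w") as fh:
        json.dump(ledger, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return cohort


def simulate_traces_stage(
    config: RunConfig, outdir: Path, cohort: pd.DataFrame | None = None
) -> list[PeakTable]:
    if cohort is None:
        cohort = read_cohort(outdir / "cohort.tsv")
    ss = _child_seed(config.seed, "traces")
    children = ss.spawn(len(cohort))
    tables: list[PeakTable] = []
    for row, child in zip(cohort.itertuples(index=False), children):
        try:
            rng = np.random.default_rng(child)
            tables.append(
                simulate_trace(row, params=config.trace, rng=rng, space="raw")
            )
            tables.append(
                ladder_trace(row.sample_id, params=config.trace, space="raw")
            )
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(
                f"stage=simulate-traces sample={row.sample_id}: {exc}"
            ) from exc
    write_peak_tables(tables, outdir / "peaks.csv", header_comment=config.header())
    return tables


def _repeat_tables(
    config: RunConfig, tables: list[PeakTable]
) -> dict[str, PeakTable]:
    """Calibrate each sample against its in-lane ladder and bin to repeats."""
    ladders = {
        t.sample_id.removesuffix(LADDER_SUFFIX): t
        for t in tables
        if t.sample_id.endswith(LADDER_SUFFIX)
    }
    out: dict[str, PeakTable] = {}
    for t in tables:
        if t.sample_id.endswith(LADDER_SUFFIX):
            continue
        try:
            if t.space == "raw":
                if t.sample_id not in ladders:
                    raise CalibrationErrorMissing(t.sample_id)
                cal = calibrate(ladders[t.sample_id], GENESCAN_500)
                t = PeakTable(
                    sample_id=t.sample_id,
                    space="bp",
                    positions=cal(t.positions),
                    heights=t.heights,
                )
            if t.space == "bp":
                t = peaks_to_repeat_space(t, flank_bp=config.flank_bp)
            out[t.sample_id] = t
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage=call sample={t.sample_id}: {exc}") from exc
    return out


class CalibrationErrorMissing(ValueError):
    def __init__(self, sample_id: str):
        super().__init__(f"no in-lane ladder found for sample {sample_id!r}")


def call_stage(
    config: RunConfig, outdir: Path, tables: list[PeakTable] | None = None
):
    if tables is None:
        tables = read_peak_tables(outdir / "peaks.csv")
    repeat_tables = _repeat_tables(config, tables)
    calls = []
    for sid, table in repeat_tables.items():
        try:
            calls.append(call_alleles(table, params=config.calling))
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage=call sample={sid}: {exc}") from exc
    write_calls(calls, outdir / "called.tsv", header_comment=config.header())
    return calls, repeat_tables


def ei_stage(
    config: RunConfig,
    outdir: Path,
    calls=None,
    repeat_tables: dict[str, PeakTable] | None = None,
):
    if calls is None or repeat_tables is None:
        tables = read_peak_tables(outdir / "peaks.csv")
        repeat_tables = _repeat_tables(config, tables)
        called_df = read_calls(outdir / "called.tsv")
        calls = list(called_df.itertuples(index=False))
    results = []
    for call in calls:
        try:
            results.append(
                expansion_index_for_allele(
                    repeat_tables[call.sample_id],
                    anchor_allele=int(call.allele_b),
                    c=config.ei_threshold,
                )
            )
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage=ei sample={call.sample_id}: {exc}") from exc
    frame = ei_results_to_frame(results)
    with open(outdir / "ei.tsv", "w") as fh:
        fh.write(f"# {config.header()}\n")
        frame.to_csv(fh, sep="\t", index=False)
    return results


def stats_stage(config: RunConfig, outdir: Path) -> dict[str, pd.DataFrame]:
    cohort = read_cohort(outdir / "cohort.tsv")
    called = read_calls(outdir / "called.tsv")
    ei = pd.read_csv(outdir / "ei.tsv", sep="\t", comment="#")
    try:
        merged = called.merge(
            cohort[["sample_id", "group"]], on="sample_id", validate="1:1"
        )
        ei_by_sample = ei.set_index("sample_id")["ei"]
        table1 = table_one(merged, ei_by_sample=ei_by_sample)
        comparisons = compare_to_controls(
            merged,
            control_label=config.control_label,
            alpha=config.alpha,
            m_comparisons=config.m_comparisons,
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage=stats: {exc}") from exc
    for name, frame in (("table1.tsv", table1), ("comparisons.tsv", comparisons)):
        with open(outdir / name, "w") as fh:
            fh.write(f"# {config.header()}\n")
            frame.to_csv(fh, sep="\t", index=False)
    manifest = {
        "package": "httcag",
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": int(config.seed),
        "outputs": [
            "cohort.tsv",
            "cohort_ledger.json",
            "peaks.csv",
            "called.tsv",
            "ei.tsv",
            "table1.tsv",
            "comparisons.tsv",
        ],
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"table1": table1, "comparisons": comparisons}


def run_all(config: RunConfig, outdir) -> dict[str, pd.DataFrame]:
    """Run every stage; returns the stats tables. Deterministic per config+seed."""
    outdir = Path(outdir)
    cohort = simulate_cohort_stage(config, outdir)
    tables = simulate_traces_stage(config, outdir, cohort=cohort)
    calls, repeat_tables = call_stage(config, outdir, tables=tables)
    ei_stage(config, outdir, calls=calls, repeat_tables=repeat_tables)
    return stats_stage(config, outdir)
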