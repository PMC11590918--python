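"""Full validation battery orchestration and the machine-readable report.

:func:`run_full_validation` executes any subset of the four validation
blocks — stationary-tag reliability, centroid precision, proximity
concordance, and the moving-rig test — over in-memory inputs and assembles
a schema-valid :class:`ValidationReport` (pydantic models; the JSON schema
is available from :func:`report_json_schema`).  Numbers in the report are
bit-identical to the constituent modules' outputs; rounding happens only in
the optional ``display`` rendering (percent to 2 decimals, metres to 3).
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from pydantic import BaseModel

from . import __version__
from .data_model import BarnLayout, ObserverRecord, TagStream
from .precision import (
    DEFAULT_THRESHOLDS,
    centroid_distances,
    pooled_exceedance_shares,
    stratified_precision,
)
from .proximity import classify_concordance, ps_proximity_series
from .reliability import interval_stats, reliability_rate
from .rig import match_same_second, rig_distance_summary

__all__ = [
    "RunConfig",
    "ValidationReport",
    "run_full_validation",
    "report_json_schema",
    "render_display",
]


# ---------------------------------------------------------------------------
# Report schema (pydantic = shipped JSON schema + validation on construction)
# ---------------------------------------------------------------------------


class TagReliability(BaseModel):
    tag_id: str
    period_label: str
    actual_count: int
    expected_count: int
    rate_pct: float


class ReliabilityBlock(BaseModel):
    per_tag: list[TagReliability]
    pooled_mean_pct: float
    pooled_sd_pct: float
    min_pct: float
    max_pct: float
    by_period: dict[str, float]  # label -> mean rate


class IntervalBlock(BaseModel):
    n_diffs: int
    mean_s: float
    sd_s: float
    median_s: float
    p95_s: float
    max_s: float
    top_quantile: float
    top_quantile_threshold_s: float
    per_tag_share_of_long_delays_pct: dict[str, float]


class TagPrecision(BaseModel):
    tag_id: str
    group_key: str
    period_label: str
    n: int
    mean_m: float
    sd_m: float
    min_m: float
    max_m: float
    exceedance_pct: dict[str, float]  # str(threshold) -> percent


class PrecisionStratum(BaseModel):
    n: int
    mean_m: float
    sd_m: float
    min_m: float
    max_m: float
    exceedance_pct: dict[str, float]
    per_tag_share_of_gross_errors_pct: dict[str, float]


class PrecisionBlock(BaseModel):
    per_group: list[TagPrecision]
    pooled: PrecisionStratum
    by_period: dict[str, PrecisionStratum]


class ProximityBlock(BaseModel):
    n_observer_cases: int
    accuracy_pct: float
    scenario_counts: dict[str, int]
    error_duration_by_scenario_s: dict[str, float]
    error_duration_by_tag_s: dict[str, float]
    total_error_duration_s: float
    focal_reliability_pct: float


class RigPair(BaseModel):
    tag_id: str
    n: int
    mean_m: float
    sd_m: float
    min_m: float
    max_m: float


class RigBlock(BaseModel):
    n_triples: int
    nominal_m: float
    tolerance_m: float
    rule: str
    pairs: dict[str, RigPair]
    pct_within: float
    reliability_pct: dict[str, float]


class Provenance(BaseModel):
    package_version: str
    seeds: dict[str, int] = {}
    input_digests: dict[str, str] = {}
    elapsed_s: dict[str, float] = {}


class ValidationReport(BaseModel):
    """Machine-readable twin of the study's summary table."""

    reliability: ReliabilityBlock | str = "not run"
    intervals: IntervalBlock | str = "not run"
    precision: PrecisionBlock | str = "not run"
    proximity: ProximityBlock | str = "not run"
    rig: RigBlock | str = "not run"
    provenance: Provenance


def report_json_schema() -> dict:
    """JSON schema of the validation report (shipped with the package)."""
    return ValidationReport.model_json_schema()


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Inputs for the validation battery; leave a block's inputs None to skip it.

    The rig block requires all three role streams; inconsistent
    configurations fail before any computation.
    """

    stationary_streams: Sequence[TagStream] | None = None
    long_quantile: float = 0.99
    precision_group_by: str = "day"
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS

    focal_stream: TagStream | None = None
    observer_records: Sequence[ObserverRecord] | None = None
    layout: BarnLayout | None = None
    radius: float = 2.0
    protocol_grid: float = 15.0

    rig_streams: Mapping[str, TagStream] | None = None  # roles lower/middle/upper
    rig_nominal: float = 0.3
    rig_tolerance: float = 0.3
    rig_rule: str = "deviation"

    seeds: Mapping[str, int] = field(default_factory=dict)
    input_digests: Mapping[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        if self.stationary_streams is None and self.focal_stream is None and self.rig_streams is None:
            raise ValueError("configuration names no inputs for any block")
        if self.focal_stream is not None:
            if self.observer_records is None or self.layout is None:
                raise ValueError("proximity block needs focal stream, observer records and layout")
        if self.rig_streams is not None:
            missing = {"lower", "middle", "upper"} - set(self.rig_streams)
            if missing:
                raise ValueError(f"rig block missing roles: {sorted(missing)}")


def file_digest(path) -> str:
    """sha256 of an input file, for report provenance."""
    return hashlib.sha256(open(path, "rb").read()).hexdigest()


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def _precision_stratum(summary) -> PrecisionStratum:
    return PrecisionStratum(
        n=summary.n,
        mean_m=summary.mean,
        sd_m=summary.sd,
        min_m=summary.min,
        max_m=summary.max,
        exceedance_pct={str(k): v for k, v in summary.exceedance.items()},
        per_tag_share_of_gross_errors_pct=dict(summary.per_tag_share_of_gross_errors),
    )


def run_full_validation(config: RunConfig, quiet: bool = True) -> ValidationReport:
    """Execute the configured validation blocks and assemble the report.

    Deterministic given identical inputs and seeds; block numbers are the
    constituent modules' outputs without re-rounding.
    """
    config.validate()
    elapsed: dict[str, float] = {}
    blocks: dict = {}

    def log(block: str, msg: str) -> None:
        if not quiet:
            print(f"[rtlsval] {block}: {msg}")

    if config.stationary_streams is not None:
        t0 = time.perf_counter()
        streams = list(config.stationary_streams)
        rel = [reliability_rate(s) for s in streams]
        rates = np.array([r.rate for r in rel])
        by_period: dict[str, list[float]] = {}
        for r in rel:
            by_period.setdefault(r.period_label, []).append(r.rate)
        blocks["reliability"] = ReliabilityBlock(
            per_tag=[
                TagReliability(
                    tag_id=r.tag_id,
                    period_label=r.period_label,
                    actual_count=r.actual_count,
                    expected_count=r.expected_count,
                    rate_pct=r.rate,
                )
                for r in rel
            ],
            pooled_mean_pct=float(rates.mean()),
            pooled_sd_pct=float(rates.std(ddof=1)) if rates.size > 1 else 0.0,
            min_pct=float(rates.min()),
            max_pct=float(rates.max()),
            by_period={k: float(np.mean(v)) for k, v in by_period.items()},
        )
        ist = interval_stats(streams, long_quantile=config.long_quantile)
        blocks["intervals"] = IntervalBlock(
            n_diffs=ist.n_diffs,
            mean_s=ist.mean,
            sd_s=ist.sd,
            median_s=ist.median,
            p95_s=ist.p95,
            max_s=ist.max,
            top_quantile=ist.top_quantile,
            top_quantile_threshold_s=ist.top_quantile_threshold,
            per_tag_share_of_long_delays_pct=dict(ist.per_tag_share_of_long_delays),
        )
        results = []
        for s in streams:
            results.extend(
                centroid_distances(s, group_by=config.precision_group_by, thresholds=config.thresholds)
            )
        strata = stratified_precision(results, thresholds=config.thresholds)
        pooled_dist = np.concatenate([r.distances for r in results])
        pooled = PrecisionStratum(
            n=int(pooled_dist.size),
            mean_m=float(pooled_dist.mean()),
            sd_m=float(pooled_dist.std(ddof=1)) if pooled_dist.size > 1 else 0.0,
            min_m=float(pooled_dist.min()),
            max_m=float(pooled_dist.max()),
            exceedance_pct={
                str(float(th)): 100.0 * float((pooled_dist > th).mean())
                for th in sorted(config.thresholds)
            },
            per_tag_share_of_gross_errors_pct=pooled_exceedance_shares(
                results, max(config.thresholds)
            ),
        )
        blocks["precision"] = PrecisionBlock(
            per_group=[
                TagPrecision(
                    tag_id=r.tag_id,
                    group_key=r.group_key,
                    period_label=r.period_label,
                    n=int(r.distances.size),
                    mean_m=r.mean,
                    sd_m=r.sd,
                    min_m=r.min,
                    max_m=r.max,
                    exceedance_pct={str(k): v for k, v in r.exceedance.items()},
                )
                for r in results
            ],
            pooled=pooled,
            by_period={k: _precision_stratum(v) for k, v in strata.items()},
        )
        elapsed["stationary"] = time.perf_counter() - t0
        log("stationary", f"{len(streams)} streams in {elapsed['stationary']:.2f}s")

    if config.focal_stream is not None:
        t0 = time.perf_counter()
        series = ps_proximity_series(config.focal_stream, config.layout, radius=config.radius)
        rep = classify_concordance(series, config.observer_records, grid=config.protocol_grid)
        s = rep.summary
        blocks["proximity"] = ProximityBlock(
            n_observer_cases=s.n_observer_cases,
            accuracy_pct=s.accuracy,
            scenario_counts={str(k): v for k, v in s.scenario_counts.items()},
            error_duration_by_scenario_s={str(k): v for k, v in s.error_duration_by_scenario.items()},
            error_duration_by_tag_s=dict(s.error_duration_by_tag),
            total_error_duration_s=s.total_error_duration,
            focal_reliability_pct=reliability_rate(config.focal_stream).rate,
        )
        elapsed["proximity"] = time.perf_counter() - t0
        log("proximity", f"{len(series)} fixes, {s.n_observer_cases} cases in {elapsed['proximity']:.2f}s")

    if config.rig_streams is not None:
        t0 = time.perf_counter()
        triples = match_same_second(
            lower=config.rig_streams["lower"],
            middle=config.rig_streams["middle"],
            upper=config.rig_streams["upper"],
        )
        summary = rig_distance_summary(
            triples,
            nominal=config.rig_nominal,
            tolerance=config.rig_tolerance,
            rule=config.rig_rule,
            streams=config.rig_streams,
        )
        blocks["rig"] = RigBlock(
            n_triples=summary.n_triples,
            nominal_m=summary.nominal,
            tolerance_m=summary.tolerance,
            rule=summary.rule,
            pairs={
                k: RigPair(
                    tag_id=v.tag_id, n=v.n, mean_m=v.mean, sd_m=v.sd, min_m=v.min, max_m=v.max
                )
                for k, v in summary.pair_stats.items()
            },
            pct_within=summary.pct_within,
            reliability_pct=dict(summary.reliability or {}),
        )
        elapsed["rig"] = time.perf_counter() - t0
        log("rig", f"{summary.n_triples} triples in {elapsed['rig']:.2f}s")

    return ValidationReport(
        **blocks,
        provenance=Provenance(
            package_version=__version__,
            seeds=dict(config.seeds),
            input_digests=dict(config.input_digests),
            elapsed_s=elapsed,
        ),
    )


def _round_floats(obj, pct_keys: bool, nd_pct: int = 2, nd_m: int = 3):
    if isinstance(obj, dict):
        return {
            k: _round_floats(v, pct_keys=str(k).endswith(("pct", "_s")) or "pct" in str(k))
            for k, v in obj.items()
        }
    if isinstance(obj, list):
        return [_round_floats(v, pct_keys) for v in obj]
    if isinstance(obj, float):
        return round(obj, nd_pct if pct_keys else nd_m)
    return obj


def render_display(report: ValidationReport) -> dict:
    """Rounded rendering of a report: percent/seconds to 2 decimals, metres to 3.

    The full-precision values stay in the report itself; this is a
    presentation view only.
    """
    return _round_floats(report.model_dump(), pct_keys=False)
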