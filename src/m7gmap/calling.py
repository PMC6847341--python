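"""Per-position analysis, filtering and candidate m7G calling.

The pipeline walks a multi-sample mpileup file with a treated/control sample
design, estimates error-aware mutation frequencies per condition, computes the
rate difference delta = f_treated - f_control and the between/within LRT
p-values, then applies the depth, control-rate and replicate-consistency
filters before calling candidates at the delta and p-value cutoffs. Default
thresholds: combined depth must exceed 1500 across samples (500 in
single-replicate mode), mean control-replicate frequency below 1%,
within-replicate p-values at or above 1e-5, and calls require
delta >= 0.5% with a between-group p below 1e-50 at G positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Optional, TextIO, Union

import numpy as np
import pandas as pd

from .error_model import ObservationSet, estimate_rate_em
from .pileup_io import PileupSite, parse_mpileup
from .stats import GroupData, NEG10LOG10_CAP, lrt_between, lrt_within, mutation_rate_difference

__all__ = [
    "SampleDesign",
    "CallingThresholds",
    "SiteResult",
    "analyze_position",
    "apply_filters",
    "call_candidates",
    "run_calling",
    "results_to_frame",
    "write_results_tsv",
    "write_bed6",
]

FLAG_LOW_DEPTH = "low_depth"
FLAG_HIGH_CONTROL_RATE = "high_control_rate"
FLAG_REPLICATE_INCONSISTENT = "replicate_inconsistent"
FLAG_UNTESTABLE = "untestable"


@dataclass(frozen=True)
class SampleDesign:
    """Assignment of mpileup sample columns (0-based) to conditions."""

    treated: tuple[int, ...]
    control: tuple[int, ...]

    def __post_init__(self):
        t, c = tuple(self.treated), tuple(self.control)
        object.__setattr__(self, "treated", t)
        object.__setattr__(self, "control", c)
        if not t or not c:
            raise ValueError("need at least one treated and one control sample")
        all_idx = t + c
        if len(set(all_idx)) != len(all_idx):
            raise ValueError("sample indices must be unique across conditions")
        if min(all_idx) < 0:
            raise ValueError("sample indices are 0-based and must be >= 0")

    @property
    def n_samples_min(self) -> int:
        return max(self.treated + self.control) + 1

    @property
    def single_replicate(self) -> bool:
        return len(self.treated) == 1 and len(self.control) == 1

    @classmethod
    def from_one_based(cls, treated: Iterable[int], control: Iterable[int]) -> "SampleDesign":
        return cls(tuple(i - 1 for i in treated), tuple(i - 1 for i in control))


@dataclass(frozen=True)
class CallingThresholds:
    """Filter and calling cutoffs (defaults as used for tRNA/mRNA analyses)."""

    min_depth_combined: int = 1500  # combined depth must exceed this
    min_depth_single: int = 500  # single-replicate (rRNA-style) mode
    max_control_rate: float = 0.01  # mean control-replicate frequency must be below
    within_p_floor: float = 1e-5  # replicate-inconsistency cutoff
    min_delta: float = 0.005  # rate-difference cutoff for calling
    max_between_p: float = 1e-50  # p-value cutoff for calling
    g_only: bool = True  # restrict calls to reference G positions

    def __post_init__(self):
        if self.min_delta < 0:
            raise ValueError("min_delta must be >= 0")
        for name in ("max_control_rate", "within_p_floor", "max_between_p"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class SiteResult:
    """Per-position statistics row (the caller's primary output record)."""

    reference_name: str
    position: int
    reference_base: str
    depth_treated: int
    depth_control: int
    f_treated: float
    f_control: float
    delta: float
    p_between: float
    neg10log10_p: float
    p_within_treated: float
    p_within_control: float
    control_rate_mean: float
    filter_flags: set[str] = field(default_factory=set)

    @property
    def passed_filters(self) -> bool:
        return not self.filter_flags


def _group(site: PileupSite, indices: tuple[int, ...]) -> GroupData:
    return GroupData(
        [ObservationSet.from_arrays(*site.sample_arrays(i)[:2]) for i in indices]
    )


def analyze_position(site: PileupSite, design: SampleDesign) -> SiteResult:
    """Estimate rates and run both LRTs for one pileup position."""
    if len(site.samples) < design.n_samples_min:
        raise ValueError(
            f"design references sample {design.n_samples_min} but file has "
            f"{len(site.samples)} samples"
        )
    treated = _group(site, design.treated)
    control = _group(site, design.control)
    nan = float("nan")
    res = SiteResult(
        reference_name=site.reference_name,
        position=site.position,
        reference_base=site.reference_base,
        depth_treated=treated.n_obs,
        depth_control=control.n_obs,
        f_treated=nan,
        f_control=nan,
        delta=nan,
        p_between=nan,
        neg10log10_p=nan,
        p_within_treated=nan,
        p_within_control=nan,
        control_rate_mean=nan,
    )
    if treated.n_obs == 0 or control.n_obs == 0:
        res.filter_flags.add(FLAG_UNTESTABLE)
        return res
    res.f_treated = estimate_rate_em(treated.pooled()).f_hat
    res.f_control = estimate_rate_em(control.pooled()).f_hat
    res.delta = mutation_rate_difference(res.f_treated, res.f_control)
    rep_rates = [
        estimate_rate_em(r).f_hat for r in control.replicates if r.n_obs > 0
    ]
    res.control_rate_mean = float(np.mean(rep_rates)) if rep_rates else nan
    between = lrt_between(treated, control)
    if between is not None:
        res.p_between = between.p_value
        res.neg10log10_p = between.neg10log10_p
    wt = lrt_within(treated)
    if wt is not None:
        res.p_within_treated = wt.p_value
    wc = lrt_within(control)
    if wc is not None:
        res.p_within_control = wc.p_value
    return res


def apply_filters(
    results: Iterable[SiteResult],
    thresholds: CallingThresholds = CallingThresholds(),
    single_replicate: bool = False,
) -> Iterator[SiteResult]:
    """Set filter flags on each result (flags are independent of each other).

    A position passes the depth filter only if the combined treated + control
    depth strictly exceeds the threshold; the control-rate filter requires the
    mean per-replicate control frequency to be strictly below its cutoff; the
    consistency filter rejects within-replicate p-values below the floor.
    """
    min_depth = (
        thresholds.min_depth_single if single_replicate else thresholds.min_depth_combined
    )
    for r in results:
        if not r.depth_treated + r.depth_control > min_depth:
            r.filter_flags.add(FLAG_LOW_DEPTH)
        if not math.isnan(r.control_rate_mean) and not (
            r.control_rate_mean < thresholds.max_control_rate
        ):
            r.filter_flags.add(FLAG_HIGH_CONTROL_RATE)
        for p in (r.p_within_treated, r.p_within_control):
            if not math.isnan(p) and p < thresholds.within_p_floor:
                r.filter_flags.add(FLAG_REPLICATE_INCONSISTENT)
        yield r


def is_called(r: SiteResult, thresholds: CallingThresholds = CallingThresholds()) -> bool:
    if r.filter_flags:
        return False
    if math.isnan(r.delta) or math.isnan(r.p_between):
        return False
    if thresholds.g_only and r.reference_base.upper() != "G":
        return False
    return r.delta >= thresholds.min_delta and r.p_between < thresholds.max_between_p


def call_candidates(
    filtered: Iterable[SiteResult],
    thresholds: CallingThresholds = CallingThresholds(),
) -> list[SiteResult]:
    """Candidate modified positions among filter-passing sites."""
    return [r for r in filtered if is_called(r, thresholds)]


def run_calling(
    mpileup: Union[str, TextIO],
    design: SampleDesign,
    thresholds: CallingThresholds = CallingThresholds(),
    single_replicate: Optional[bool] = None,
) -> pd.DataFrame:
    """Full pipeline over an mpileup file or stream; returns the results table.

    ``single_replicate`` defaults to auto-detection from the design (one
    treated and one control sample), switching the depth threshold to the
    single-replicate default and leaving within-replicate p-values undefined.
    """
    if single_replicate is None:
        single_replicate = design.single_replicate
    close = False
    if isinstance(mpileup, str):
        mpileup = open(mpileup)
        close = True
    try:
        sites = parse_mpileup(mpileup)
        results = (analyze_position(s, design) for s in sites)
        flagged = list(apply_filters(results, thresholds, single_replicate))
    finally:
        if close:
            mpileup.close()
    return results_to_frame(flagged, thresholds)


_COLUMNS = [
    "reference",
    "position",
    "ref_base",
    "depth_treated",
    "depth_control",
    "f_treated",
    "f_control",
    "delta",
    "p_between",
    "neg10log10_p",
    "p_within_treated",
    "p_within_control",
    "control_rate_mean",
    "filters",
    "called",
]


def results_to_frame(
    results: list[SiteResult], thresholds: CallingThresholds = CallingThresholds()
) -> pd.DataFrame:
    rows = [
        (
            r.reference_name,
            r.position,
            r.reference_base,
            r.depth_treated,
            r.depth_control,
            r.f_treated,
            r.f_control,
            r.delta,
            r.p_between,
            r.neg10log10_p,
            r.p_within_treated,
            r.p_within_control,
            r.control_rate_mean,
            ",".join(sorted(r.filter_flags)) or "PASS",
            is_called(r, thresholds),
        )
        for r in results
    ]
    return pd.DataFrame(rows, columns=_COLUMNS)


def write_results_tsv(frame: pd.DataFrame, out: Union[str, IO[str]]) -> None:
    """Write the results table as TSV (deterministic float formatting)."""
    frame.to_csv(out, sep="\t", index=False, float_format="%.6g")


def write_bed6(frame: pd.DataFrame, out: Union[str, IO[str]]) -> None:
    """Export called sites as BED6 (conversion to 0-based half-open here only)."""
    called = frame[frame["called"]]
    bed = pd.DataFrame(
        {
            "chrom": called["reference"],
            "start": called["position"] - 1,
            "end": called["position"],
            "name": [
                f"m7G_{r}_{p}" for r, p in zip(called["reference"], called["position"])
            ],
            "score": np.minimum(called["neg10log10_p"], 1000).round().astype(int),
            "strand": ".",
        }
    )
    bed.to_csv(out, sep="\t", index=False, header=False)
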