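"""Truncation sensitivity analyses and paired pre/post change reports.

Ramp tests stopped short of a symptomatic maximum are emulated by truncating
the ramp phase — either to a fraction of its breaths or to a VO2 ceiling —
and recomputing every derived index. This quantifies how much each estimator
depends on test duration (the VCO2-based exponential threshold is the most
duration-sensitive index; the VE-based one much less so).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data import CpxTest, select_ramp
from .errors import DomainError, InsufficientDataError
from .estimators import FLAG_INSUFFICIENT, VatEstimates, evaluate_test

#: rolling-mean window (breaths) used to locate a VO2 ceiling crossing
VO2_CEILING_WINDOW = 8


@dataclass(frozen=True)
class TruncationSpec:
    """How to shorten a test.

    mode "fraction_of_ramp": keep the first ceil(fraction * n) ramp breaths.
    mode "vo2_ceiling": keep ramp breaths up to the first crossing of
    ``vo2_limit`` (mL/min) by an 8-breath rolling mean of VO2; the rolling
    mean tames raw breath-to-breath VO2 non-monotonicity.
    """

    mode: str
    fraction: float | None = None
    vo2_limit: float | None = None

    def __post_init__(self) -> None:
        if self.mode == "fraction_of_ramp":
            if self.fraction is None or not 0 < self.fraction <= 1:
                raise DomainError("fraction_of_ramp needs 0 < fraction <= 1")
            if self.vo2_limit is not None:
                raise DomainError("vo2_limit is not a fraction_of_ramp field")
        elif self.mode == "vo2_ceiling":
            if self.vo2_limit is None or not self.vo2_limit > 0:
                raise DomainError("vo2_ceiling needs vo2_limit > 0")
            if self.fraction is not None:
                raise DomainError("fraction is not a vo2_ceiling field")
        else:
            raise DomainError(f"unknown truncation mode {self.mode!r}")


def truncate(test: CpxTest, spec: TruncationSpec) -> CpxTest:
    """Shorten the ramp phase of a test; a pure sample filter.

    Rest and warmup samples are always retained unchanged; recovery samples
    are dropped whenever the ramp is actually shortened (they would follow a
    portion of the test that no longer exists). Sample values are never
    altered. Errors when fewer than 10 ramp samples would remain.
    """
    ramp = select_ramp(test)
    n = len(ramp)
    if spec.mode == "fraction_of_ramp":
        kept = math.ceil(spec.fraction * n)
    else:
        vo2 = pd.Series([s.vo2 for s in ramp], dtype=float)
        roll = vo2.rolling(VO2_CEILING_WINDOW, min_periods=1).mean()
        over = np.flatnonzero(roll.to_numpy() > spec.vo2_limit)
        kept = int(over[0]) + 1 if len(over) else n
    if kept >= n:
        return test
    if kept < 10:
        raise InsufficientDataError(
            f"truncation keeps {kept} ramp samples; need >= 10"
        )
    kept_ids = set(id(s) for s in ramp[:kept])
    samples = tuple(
        s for s in test.samples
        if s.phase in ("rest", "warmup") or id(s) in kept_ids
    )
    return replace(test, samples=samples)


def truncation_effect(
    test: CpxTest,
    spec: TruncationSpec,
    *,
    method: str = "log-linear",
) -> dict:
    """Full vs truncated estimates with percent change per index.

    percent change = 100 * (truncated - full) / full, reported for every
    index field that is defined in both runs. Estimator flags propagate; a
    truncation too short to fit yields an insufficient-data flagged record
    rather than an exception.
    """
    full = evaluate_test(test, method=method)
    try:
        short = evaluate_test(truncate(test, spec), method=method)
    except InsufficientDataError:
        short = VatEstimates(subject_id=test.meta.subject_id,
                             qc_flags=frozenset({FLAG_INSUFFICIENT}))
    change: dict[str, float | None] = {}
    for name in VatEstimates.INDEX_FIELDS:
        f, s = getattr(full, name), getattr(short, name)
        change[name] = 100.0 * (s - f) / f if (f and s is not None) else None
    return {"full": full, "truncated": short, "percent_change": change}


def paired_change_report(
    pre: Sequence[VatEstimates],
    post: Sequence[VatEstimates],
    fields: Sequence[str] = VatEstimates.INDEX_FIELDS,
) -> pd.DataFrame:
    """Paired pre/post comparison of derived indices, matched by subject id.

    For each index: mean before, mean after, mean paired difference
    (post - pre), two-sided paired t-test p, and the number of complete
    pairs. Pairs missing either member are dropped per index; an index with
    no complete pairs gets NaN statistics and n = 0.
    """
    pre_by_id = {e.subject_id: e for e in pre}
    post_by_id = {e.subject_id: e for e in post}
    common = [sid for sid in pre_by_id if sid in post_by_id]
    rows = []
    for name in fields:
        a = np.array([np.nan if (v := getattr(pre_by_id[s], name)) is None
                      else v for s in common], dtype=float)
        b = np.array([np.nan if (v := getattr(post_by_id[s], name)) is None
                      else v for s in common], dtype=float)
        keep = np.isfinite(a) & np.isfinite(b)
        a, b = a[keep], b[keep]
        n = int(keep.sum())
        if n == 0:
            rows.append({"index": name, "mean_pre": np.nan, "mean_post": np.nan,
                         "mean_diff": np.nan, "p": np.nan, "n": 0})
            continue
        if n >= 2 and np.std(b - a) > 0:
            p = float(sps.ttest_rel(b, a).pvalue)
        else:
            p = np.nan
        rows.append({
            "index": name,
            "mean_pre": float(np.mean(a)),
            "mean_post": float(np.mean(b)),
            "mean_diff": float(np.mean(b - a)),
            "p": p,
            "n": n,
        })
    return pd.DataFrame(rows).set_index("index")
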