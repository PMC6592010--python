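"""Data model and I/O for breath-by-breath cardiopulmonary exercise (CPX) tests.

A test is an ordered sequence of breaths, each carrying oxygen uptake (VO2,
mL/min STPD), carbon-dioxide output (VCO2, mL/min STPD) and minute ventilation
(VE, L/min BTPS), plus optional heart rate and work rate. Breaths are labelled
with a protocol phase (rest, warmup, ramp, recovery); all fitting operations
consume only the ramp phase. Tables are plain CSV with one header row and
canonical lower-case column names; a column map and unit declarations
accommodate vendor exports.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, DomainError, FormatError, InsufficientDataError

PHASES = ("rest", "warmup", "ramp", "recovery")
_PHASE_RANK = {p: i for i, p in enumerate(PHASES)}

REQUIRED_COLUMNS = ("t", "vo2", "vco2", "ve")
OPTIONAL_COLUMNS = ("hr", "work_rate", "phase")

# multiplicative factors to the canonical unit of each channel
_UNIT_FACTORS = {
    "vo2": {"ml/min": 1.0, "l/min": 1000.0},
    "vco2": {"ml/min": 1.0, "l/min": 1000.0},
    "ve": {"l/min": 1.0, "ml/min": 1e-3},
    "t": {"s": 1.0, "min": 60.0},
}


@dataclass(frozen=True)
class BreathSample:
    """One breath's gas-exchange measurement.

    t is seconds from test start; vo2/vco2 in mL/min, ve in L/min.
    """

    t: float
    vo2: float
    vco2: float
    ve: float
    hr: float | None = None
    work_rate: float | None = None
    phase: str = "ramp"

    def __post_init__(self) -> None:
        if not math.isfinite(self.t):
            raise DataError(f"non-finite breath time {self.t!r}")
        for name in ("vo2", "vco2", "ve"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise DataError(f"{name} must be finite and > 0, got {v!r}")
        if self.phase not in _PHASE_RANK:
            raise DataError(
                f"unknown phase {self.phase!r}; expected one of {PHASES}"
            )


@dataclass(frozen=True)
class SubjectMeta:
    """Per-subject metadata; all physiological fields optional.

    vvat is an externally (visually) determined ventilatory anaerobic
    threshold in mL/min; it is consumed as an input, never computed here.
    """

    subject_id: str = ""
    age: float | None = None
    sex: str = "unknown"
    weight: float | None = None
    group: str | None = None
    vvat: float | None = None

    def __post_init__(self) -> None:
        for name in ("age", "weight", "vvat"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise DataError(f"{name} must be > 0 when present, got {v!r}")
        if self.sex not in ("male", "female", "unknown"):
            raise DataError(f"sex must be male/female/unknown, got {self.sex!r}")


@dataclass(frozen=True)
class Protocol:
    """Ramp protocol description: work-rate ramp rate (W/min) and warm-up length (s)."""

    ramp_rate: float | None = None
    warmup_s: float = 120.0


@dataclass(frozen=True)
class CpxTest:
    """An ordered CPX test record: metadata, protocol and breath samples.

    Invariants enforced at construction: sample times strictly increasing and
    phases appearing in protocol order rest -> warmup -> ramp -> recovery
    (phases may be absent but never interleaved out of order).
    """

    meta: SubjectMeta = field(default_factory=SubjectMeta)
    protocol: Protocol = field(default_factory=Protocol)
    samples: tuple[BreathSample, ...] = ()
    annotations: Mapping[str, tuple] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", tuple(self.samples))
        prev_t = -math.inf
        prev_rank = 0
        for i, s in enumerate(self.samples):
            if s.t <= prev_t:
                raise DataError(
                    f"sample times must be strictly increasing; row {i} "
                    f"(t={s.t}) does not follow t={prev_t}"
                )
            rank = _PHASE_RANK[s.phase]
            if rank < prev_rank:
                raise DataError(
                    f"phase {s.phase!r} at row {i} appears after "
                    f"{PHASES[prev_rank]!r}; phases must follow {PHASES}"
                )
            prev_t, prev_rank = s.t, rank

    def __len__(self) -> int:
        return len(self.samples)

    def to_frame(self) -> pd.DataFrame:
        """Return the samples as a DataFrame in canonical columns and units."""
        rows = {
            "t": [s.t for s in self.samples],
            "vo2": [s.vo2 for s in self.samples],
            "vco2": [s.vco2 for s in self.samples],
            "ve": [s.ve for s in self.samples],
            "hr": [s.hr for s in self.samples],
            "work_rate": [s.work_rate for s in self.samples],
            "phase": [s.phase for s in self.samples],
        }
        df = pd.DataFrame(rows)
        for k, v in self.annotations.items():
            df[k] = list(v)
        return df


def select_ramp(test: CpxTest) -> list[BreathSample]:
    """Return exactly the ramp-phase samples, order preserved."""
    ramp = [s for s in test.samples if s.phase == "ramp"]
    if not ramp:
        raise InsufficientDataError("test contains no ramp-phase samples")
    return ramp


def require_ramp(test: CpxTest, n_min: int = 10) -> list[BreathSample]:
    """Ramp samples, erroring when fewer than ``n_min`` are available."""
    ramp = select_ramp(test)
    if len(ramp) < n_min:
        raise InsufficientDataError(
            f"need at least {n_min} ramp samples, found {len(ramp)}"
        )
    return ramp


def derive_ratios(samples: Sequence[BreathSample]) -> pd.DataFrame:
    """Per-breath respiratory exchange ratio and ventilatory equivalents.

    R = VCO2/VO2; ve_vo2 = 1000*VE/VO2 and ve_vco2 = 1000*VE/VCO2 (VE
    converted to mL/min so the equivalents are dimensionless). The algebraic
    identity ve_vo2 / ve_vco2 == R holds for every breath.
    """
    vo2 = np.array([s.vo2 for s in samples], dtype=float)
    vco2 = np.array([s.vco2 for s in samples], dtype=float)
    ve = np.array([s.ve for s in samples], dtype=float)
    if np.any(vo2 <= 0) or np.any(vco2 <= 0) or np.any(ve <= 0):
        raise DomainError("gas-exchange values must be strictly positive")
    return pd.DataFrame(
        {
            "t": [s.t for s in samples],
            "r": vco2 / vo2,
            "ve_vo2": ve * 1000.0 / vo2,
            "ve_vco2": ve * 1000.0 / vco2,
        }
    )


def moving_average(samples: Sequence[BreathSample], window: int) -> list[BreathSample]:
    """Optional n-breath centred moving average of the gas channels.

    Off by default throughout the package: estimators fit raw breaths.
    Timestamps, phases and the auxiliary channels are left untouched.
    """
    if window < 1:
        raise DomainError("window must be >= 1")
    if window == 1:
        return list(samples)
    out = []
    arr = {
        name: pd.Series([getattr(s, name) for s in samples], dtype=float)
        .rolling(window, center=True, min_periods=1)
        .mean()
        for name in ("vo2", "vco2", "ve")
    }
    for i, s in enumerate(samples):
        out.append(
            replace(s, vo2=arr["vo2"][i], vco2=arr["vco2"][i], ve=arr["ve"][i])
        )
    return out


def highest_values(test: CpxTest, window: int = 1) -> dict:
    """Highest (peak) values over the ramp phase.

    The highest value of each channel is the maximum of a trailing rolling
    mean of length ``window`` breaths; the default window of 1 reproduces the
    plain last-highest-value convention. Per-kg variants are present only
    when subject weight is known; HR fields only when HR was recorded.
    """
    if window < 1:
        raise DomainError("window must be >= 1")
    ramp = select_ramp(test)

    def _roll_max(values: list[float | None]) -> float | None:
        clean = [v for v in values if v is not None and math.isfinite(v)]
        if not clean:
            return None
        s = pd.Series(clean, dtype=float)
        return float(s.rolling(window, min_periods=1).mean().max())

    vo2 = _roll_max([s.vo2 for s in ramp])
    hr = _roll_max([s.hr for s in ramp])
    rer = _roll_max([s.vco2 / s.vo2 for s in ramp])
    out = {"highest_vo2": vo2, "highest_hr": hr, "highest_r": rer}
    w = test.meta.weight
    out["highest_vo2_per_kg"] = vo2 / w if (w and vo2 is not None) else None
    return out


def infer_phases(t: np.ndarray, protocol: Protocol) -> list[str]:
    """Phase labels from protocol timing when the table lacks a phase column.

    Breaths in the first ``warmup_s`` seconds are warmup, the remainder ramp.
    Negative times (pre-exercise) are labelled rest.
    """
    phases = []
    for ti in t:
        if ti < 0:
            phases.append("rest")
        elif ti < protocol.warmup_s:
            phases.append("warmup")
        else:
            phases.append("ramp")
    return phases


def read_cpx_table(
    path: str | Path,
    meta: SubjectMeta | None = None,
    *,
    protocol: Protocol | None = None,
    column_map: Mapping[str, str] | None = None,
    units: Mapping[str, str] | None = None,
) -> CpxTest:
    """Read a delimited breath table into a :class:`CpxTest`.

    Parameters
    ----------
    path
        CSV file with a header row. Required columns (after applying
        ``column_map``): t, vo2, vco2, ve. Optional: hr, work_rate, phase.
    meta, protocol
        Subject metadata and protocol; defaults used when omitted. The
        protocol drives phase inference for tables without a phase column.
    column_map
        Mapping from canonical name to the column name in the file,
        e.g. ``{"vo2": "VO2(mL/min)"}``.
    units
        Declared input units per channel (e.g. ``{"vo2": "L/min"}``);
        values are converted to the canonical units at read time.

    Rows whose numeric fields fail to parse are dropped with a warning that
    reports their 1-based data row numbers.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    if column_map:
        rename = {src: canon for canon, src in column_map.items()}
        df = df.rename(columns=rename)
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path.name}: missing required column(s) {missing}; "
            f"found {list(df.columns)}"
        )

    numeric_cols = [c for c in ("t", "vo2", "vco2", "ve", "hr", "work_rate") if c in df.columns]
    parsed = df[numeric_cols].apply(pd.to_numeric, errors="coerce")
    bad = parsed[list(REQUIRED_COLUMNS)].isna().any(axis=1)
    if bad.any():
        rows = [int(i) + 1 for i in np.flatnonzero(bad.to_numpy())]
        warnings.warn(
            f"{path.name}: dropped {len(rows)} unparsable row(s): {rows}",
            stacklevel=2,
        )
        df = df.loc[~bad]
        parsed = parsed.loc[~bad]
    if df.empty:
        raise DataError(f"{path.name}: no parsable data rows")

    if units:
        for chan, unit in units.items():
            factors = _UNIT_FACTORS.get(chan)
            if factors is None or unit.lower() not in factors:
                raise FormatError(f"unknown unit {unit!r} for channel {chan!r}")
            parsed[chan] = parsed[chan] * factors[unit.lower()]

    protocol = protocol or Protocol()
    t = parsed["t"].to_numpy(dtype=float)
    if "phase" in df.columns:
        phases = [str(p).strip().lower() for p in df["phase"]]
    else:
        phases = infer_phases(t, protocol)

    samples = []
    for i in range(len(df)):
        hr = parsed["hr"].iloc[i] if "hr" in parsed else np.nan
        wr = parsed["work_rate"].iloc[i] if "work_rate" in parsed else np.nan
        samples.append(
            BreathSample(
                t=float(t[i]),
                vo2=float(parsed["vo2"].iloc[i]),
                vco2=float(parsed["vco2"].iloc[i]),
                ve=float(parsed["ve"].iloc[i]),
                hr=None if pd.isna(hr) else float(hr),
                work_rate=None if pd.isna(wr) else float(wr),
                phase=phases[i],
            )
        )
    extra = [
        c for c in df.columns
        if c not in REQUIRED_COLUMNS and c not in OPTIONAL_COLUMNS
    ]
    annotations = {c: tuple(df[c]) for c in extra}
    return CpxTest(
        meta=meta or SubjectMeta(),
        protocol=protocol,
        samples=tuple(samples),
        annotations=annotations,
    )


def write_cpx_table(test: CpxTest, path: str | Path) -> None:
    """Write a breath table that :func:`read_cpx_table` reads back identically.

    Floats are written with shortest round-tripping representation, so a
    write -> read cycle preserves every sample to full precision.
    """
    df = test.to_frame()
    df.to_csv(path, index=False)
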