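"""Plate-reader trace I/O, initial-rate extraction and activity units.

Kinetic traces are absorbance-vs-time reads from a microplate
spectrophotometer (e.g. guaiacol oxidation followed at 470 nm, conjugated
diene formation from linoleate at 234 nm).  The initial reaction rate is
estimated as the ordinary-least-squares slope of absorbance against time
over the recorded window, expressed in delta-AU/min.

The CSV dialect is long format, one row per read:

    well_id,time_min,absorbance,wavelength_nm,compound,dose_mM,
    compound2,dose2_mM,substrate_mM,ratio,replicate

Annotation columns may be empty.  Lines starting with ``#`` are treated as
provenance comments.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (
    InputError,
    InsufficientDataError,
    ParseError,
    SchemaError,
    UnitConversionError,
)

#: one unit of lipoxygenase activity = 0.001 delta-AU/min at 234 nm
LOX_UNIT_SLOPE_AU_PER_MIN = 0.001
LOX_WAVELENGTH_NM = 234.0

REQUIRED_COLUMNS = ("well_id", "time_min", "absorbance", "wavelength_nm")
ANNOTATION_COLUMNS = (
    "compound",
    "dose_mM",
    "compound2",
    "dose2_mM",
    "substrate_mM",
    "ratio",
    "replicate",
)


@dataclass
class SampleAnnotation:
    """Experimental annotation shared by all reads of one well."""

    compound: str | None = None
    dose_mM: float | None = None
    compound2: str | None = None
    dose2_mM: float | None = None
    substrate_mM: float | None = None
    ratio: str | None = None
    replicate: int | None = None

    def as_dict(self) -> dict:
        return {
            "compound": self.compound,
            "dose_mM": self.dose_mM,
            "compound2": self.compound2,
            "dose2_mM": self.dose2_mM,
            "substrate_mM": self.substrate_mM,
            "ratio": self.ratio,
            "replicate": self.replicate,
        }


@dataclass
class KineticTrace:
    """Absorbance-vs-time trace of a single well at one wavelength."""

    well_id: str
    wavelength_nm: float
    times_min: np.ndarray
    absorbances_au: np.ndarray
    annotation: SampleAnnotation = field(default_factory=SampleAnnotation)

    def __post_init__(self):
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.absorbances_au = np.asarray(self.absorbances_au, dtype=float)
        if self.times_min.size != self.absorbances_au.size:
            raise InputError("times and absorbances must have equal length")
        if self.times_min.size < 3:
            raise InsufficientDataError(
                f"trace {self.well_id!r} has {self.times_min.size} points; >=3 required"
            )
        if np.any(np.diff(self.times_min) <= 0):
            raise InputError(f"trace {self.well_id!r}: times must be strictly increasing")

    @property
    def n_points(self) -> int:
        return int(self.times_min.size)


@dataclass
class RateMeasurement:
    """One initial rate (delta-AU/min) with its sample annotation."""

    rate: float
    intercept: float
    fit_r2: float
    n_points: int
    well_id: str = ""
    wavelength_nm: float = float("nan")
    annotation: SampleAnnotation = field(default_factory=SampleAnnotation)
    qc_pass: bool = True


def initial_rate(trace: KineticTrace, window_min: tuple[float, float] | None = None,
                 qc_r2: float = 0.90) -> RateMeasurement:
    """OLS slope of absorbance vs time (delta-AU/min), sign preserved.

    ``window_min`` restricts the fit to ``[t0, t1]``; the default uses the
    full trace.  Traces whose r-squared falls below ``qc_r2`` are flagged
    (``qc_pass=False``), never dropped.
    """
    t, a = trace.times_min, trace.absorbances_au
    if window_min is not None:
        keep = (t >= window_min[0]) & (t <= window_min[1])
        t, a = t[keep], a[keep]
    if t.size < 3:
        raise InsufficientDataError(
            f"trace {trace.well_id!r}: {t.size} points in window; >=3 required"
        )
    if np.ptp(a) == 0.0:  # flat trace: exact zero slope
        slope, intercept = 0.0, float(a[0])
    else:
        slope, intercept = np.polyfit(t, a, 1)
    resid = a - (intercept + slope * t)
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((a - a.mean()) ** 2))
    if ss_tot == 0.0:
        # flat trace: a constant fit is exact
        r2 = 1.0 if ss_res <= 1e-24 else 0.0
    else:
        r2 = max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    return RateMeasurement(
        rate=float(slope),
        intercept=float(intercept),
        fit_r2=r2,
        n_points=int(t.size),
        well_id=trace.well_id,
        wavelength_nm=trace.wavelength_nm,
        annotation=replace(trace.annotation),
        qc_pass=r2 >= qc_r2,
    )


def lox_units(rate: float, wavelength_nm: float = LOX_WAVELENGTH_NM) -> float:
    """Convert a 234 nm rate (delta-AU/min) to lipoxygenase units/min.

    One unit corresponds to an absorbance increase of 0.001 per minute at
    234 nm, so ``units = rate / 0.001``.
    """
    if wavelength_nm != LOX_WAVELENGTH_NM:
        raise UnitConversionError(
            f"LOX unit conversion requires a 234 nm read, got {wavelength_nm} nm"
        )
    return rate / LOX_UNIT_SLOPE_AU_PER_MIN


# ---------------------------------------------------------------------------
# CSV I/O


def _read_csv(path_or_buf) -> pd.DataFrame:
    return pd.read_csv(path_or_buf, comment="#", float_precision="round_trip",
                       dtype={"well_id": str, "compound": str,
                              "compound2": str, "ratio": str})


def read_traces(path_or_buf, qc_duplicates: bool = True) -> list[KineticTrace]:
    """Read long-format trace CSV into one trace per (well, wavelength).

    Raises :class:`SchemaError` on missing columns, :class:`ParseError` on
    non-numeric absorbance/time values (naming the offending row), and
    :class:`InputError` on duplicate (well, wavelength, time) reads.
    """
    df = _read_csv(path_or_buf)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trace CSV missing required column(s): {', '.join(missing)}")
    for col in ("time_min", "absorbance", "wavelength_nm"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(df.index[bad][0]) + 2  # 1-based + header line
            raise ParseError(f"non-numeric value {df.loc[bad, col].iloc[0]!r} "
                             f"in column {col!r} at CSV line {row}")
        df[col] = coerced
    dup = df.duplicated(subset=["well_id", "wavelength_nm", "time_min"], keep=False)
    if qc_duplicates and dup.any():
        r = df.loc[dup].iloc[0]
        raise InputError(
            f"duplicate read for well {r['well_id']!r} at "
            f"{r['wavelength_nm']} nm, t={r['time_min']} min"
        )
    traces = []
    for (well, wl), grp in df.groupby(["well_id", "wavelength_nm"], sort=False):
        grp = grp.sort_values("time_min")
        first = grp.iloc[0]
        ann = SampleAnnotation(
            compound=_opt_str(first.get("compound")),
            dose_mM=_opt_float(first.get("dose_mM")),
            compound2=_opt_str(first.get("compound2")),
            dose2_mM=_opt_float(first.get("dose2_mM")),
            substrate_mM=_opt_float(first.get("substrate_mM")),
            ratio=_opt_str(first.get("ratio")),
            replicate=_opt_int(first.get("replicate")),
        )
        traces.append(KineticTrace(
            well_id=str(well),
            wavelength_nm=float(wl),
            times_min=grp["time_min"].to_numpy(),
            absorbances_au=grp["absorbance"].to_numpy(),
            annotation=ann,
        ))
    return traces


def _opt_str(v):
    if v is None or (isinstance(v, float) and np.isnan(v)) or pd.isna(v):
        return None
    return str(v)


def _opt_float(v):
    if v is None or pd.isna(v):
        return None
    return float(v)


def _opt_int(v):
    if v is None or pd.isna(v):
        return None
    return int(v)


def traces_to_frame(traces: list[KineticTrace]) -> pd.DataFrame:
    rows = []
    for tr in traces:
        ann = tr.annotation.as_dict()
        for t, a in zip(tr.times_min, tr.absorbances_au):
            rows.append({"well_id": tr.well_id, "time_min": t, "absorbance": a,
                         "wavelength_nm": tr.wavelength_nm, **ann})
    return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS) + list(ANNOTATION_COLUMNS))


def write_traces(traces: list[KineticTrace], path, header_comment: str | None = None) -> None:
    df = traces_to_frame(traces)
    _write_csv(df, path, header_comment)


def rates_to_frame(rates: list[RateMeasurement]) -> pd.DataFrame:
    rows = []
    for rm in rates:
        rows.append({"well_id": rm.well_id, "wavelength_nm": rm.wavelength_nm,
                     **rm.annotation.as_dict(), "rate": rm.rate, "intercept": rm.intercept,
                     "r2": rm.fit_r2, "n_points": rm.n_points, "qc_pass": rm.qc_pass})
    return pd.DataFrame(rows)


def write_rates(rates: list[RateMeasurement] | pd.DataFrame, path,
                header_comment: str | None = None) -> None:
    df = rates if isinstance(rates, pd.DataFrame) else rates_to_frame(rates)
    _write_csv(df, path, header_comment)


def read_rates(path_or_buf) -> pd.DataFrame:
    """Read a rates CSV (as written by :func:`write_rates` or the generator)."""
    df = _read_csv(path_or_buf)
    if "rate" not in df.columns:
        raise SchemaError("rates CSV missing required column 'rate'")
    return df


def _write_csv(df: pd.DataFrame, path, header_comment: str | None) -> None:
    buf = io.StringIO()
    if header_comment:
        for line in header_comment.splitlines():
            buf.write(f"# {line}\n")
    df.to_csv(buf, index=False)
    if hasattr(path, "write"):
        path.write(buf.getvalue())
    else:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(buf.getvalue())
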