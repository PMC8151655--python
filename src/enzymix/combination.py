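"""Fixed-ratio isobolographic analysis and the combination index.

Two agents are mixed at fixed dose ratios and the mixture's dose-effect
curve is fitted on the *total* dose with the same median-effect model used
for the single agents.  At an effect level x, the total mixture dose is
split into component doses (d1, d2) by the ratio convention, and the
combination index is

    CI = d1/Dx1 + d2/Dx2 = 1/DRI1 + 1/DRI2

where Dx_i is the dose of agent i alone producing effect x and
DRI_i = Dx_i/d_i is the dose-reduction index.  CI < 1 indicates synergy,
CI = 1 Loewe additivity, CI > 1 antagonism; the refined verbal bands are
given in :data:`INTERACTION_BANDS`.  Dose-normalised isobologram
coordinates are (d1/Dx1, d2/Dx2): a point below the unit anti-diagonal is
synergistic.

Volume ratios are converted to component dose fractions assuming, by
default, equal molar stock concentrations (a 3:2 ratio gives d1 = 0.6 of
the total dose); per-component stock concentrations can be supplied when
stocks are not equimolar.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dose_response import (
    DoseEffectSeries,
    MedianEffectFit,
    dose_at_effect,
    fit_median_effect,
)
from .errors import BootstrapError, FitError, InputError

#: refined combination-index bands: (upper edge, label). A CI belongs to the
#: first band whose upper edge it does not exceed; the additive band is
#: closed on both sides ([0.90, 1.10]) so its neighbours are half-open.
INTERACTION_BANDS = (
    (0.10, "very strong synergism"),
    (0.30, "strong synergism"),
    (0.70, "synergism"),
    (0.85, "moderate synergism"),
    (0.90, "slight synergism"),
    (1.10, "nearly additive"),   # closed-closed by construction of the scan
    (1.20, "slight antagonism"),
    (1.45, "moderate antagonism"),
    (3.30, "antagonism"),
    (10.0, "strong antagonism"),
    (np.inf, "very strong antagonism"),
)


def ratio_fractions(ratio: tuple[int, int],
                    stocks_mM: tuple[float, float] = (1.0, 1.0)) -> tuple[float, float]:
    """Dose fraction of each component implied by a volume ratio.

    With stock concentrations (c1, c2) and volume ratio p:q, agent 1
    contributes f1 = p.c1/(p.c1 + q.c2) of the total mixed dose.
    """
    p, q = ratio
    if p <= 0 or q <= 0:
        raise InputError(f"ratio parts must be positive integers, got {ratio}")
    c1, c2 = stocks_mM
    if c1 <= 0 or c2 <= 0:
        raise InputError("stock concentrations must be positive")
    tot = p * c1 + q * c2
    return p * c1 / tot, q * c2 / tot


@dataclass
class MixtureSeries:
    """Fixed-ratio two-agent dose-effect data, fitted on total dose.

    ``data`` columns: ``dose_total_mM``, ``replicate``, ``fa``.
    ``fraction1`` is agent 1's share of every total dose, so component
    doses are d1 = fraction1 * total and d2 = (1 - fraction1) * total.
    """

    agent1: str
    agent2: str
    ratio: tuple[int, int]
    fraction1: float
    data: pd.DataFrame
    role: str = "inhibition"

    def __post_init__(self):
        if not (0.0 < self.fraction1 < 1.0):
            raise InputError(f"fraction1 must be in (0,1), got {self.fraction1}")
        need = {"dose_total_mM", "replicate", "fa"}
        if need - set(self.data.columns):
            raise InputError(f"mixture data needs columns {sorted(need)}")
        if (self.data["dose_total_mM"] <= 0).any():
            raise InputError("total mixture doses must be positive")

    def as_dose_effect(self) -> DoseEffectSeries:
        df = self.data.rename(columns={"dose_total_mM": "dose_mM"})
        return DoseEffectSeries(agent=f"{self.agent1}+{self.agent2}",
                                role=self.role if self.role in ("inhibition", "scavenging")
                                else "inhibition",
                                data=df[["dose_mM", "replicate", "fa"]])


def mixture_from_rates(rates: pd.DataFrame, agent1: str, agent2: str,
                       ratio: tuple[int, int],
                       stocks_mM: tuple[float, float] = (1.0, 1.0),
                       control_rate: float | None = None,
                       role: str = "inhibition") -> MixtureSeries:
    """Build a mixture series from a rates table with dose_mM/dose2_mM columns."""
    df = rates.copy()
    df["dose_mM"] = df["dose_mM"].fillna(0.0)
    df["dose2_mM"] = df.get("dose2_mM", pd.Series(0.0, index=df.index)).fillna(0.0)
    if control_rate is None:
        ctrl = df.loc[(df["dose_mM"] == 0) & (df["dose2_mM"] == 0), "rate"]
        if ctrl.empty:
            raise InputError("no control rows (both doses 0) and no control_rate given")
        control_rate = float(ctrl.mean())
    if control_rate <= 0:
        raise InputError("control rate must be positive")
    dosed = df[(df["dose_mM"] > 0) & (df["dose2_mM"] > 0)].copy()
    dosed["dose_total_mM"] = dosed["dose_mM"] + dosed["dose2_mM"]
    dosed["fa"] = 1.0 - dosed["rate"] / control_rate
    f1, _ = ratio_fractions(ratio, stocks_mM)
    return MixtureSeries(agent1=agent1, agent2=agent2, ratio=ratio, fraction1=f1,
                         data=dosed[["dose_total_mM", "replicate", "fa"]]
                         .reset_index(drop=True), role=role)


@dataclass
class CombinationResult:
    """CI, DRIs, isobologram coordinates and interaction label at one x."""

    agent1: str
    agent2: str
    ratio: tuple[int, int]
    x: float
    dx1: float
    dx2: float
    d1: float
    d2: float
    ci: float
    dri1: float
    dri2: float
    label: str
    ci_sd: float | None = None

    @property
    def isobole_point(self) -> tuple[float, float]:
        return (self.d1 / self.dx1, self.d2 / self.dx2)


def classify_interaction(ci: float) -> str:
    """Verbal interaction class for a combination index."""
    if not np.isfinite(ci) or ci <= 0:
        raise InputError(f"combination index must be a positive number, got {ci}")
    for edge, label in INTERACTION_BANDS:
        if ci <= edge:
            return label
    raise AssertionError("unreachable")


def combination_index(single1: MedianEffectFit, single2: MedianEffectFit,
                      mixture: MixtureSeries, x: float = 0.5,
                      mixture_fit: MedianEffectFit | None = None) -> CombinationResult:
    """Combination index of a fixed-ratio mixture at effect level x.

    The mixture's median-effect curve (fitted on total dose) gives the
    total dose achieving x; the ratio convention splits it into component
    doses; the single-agent fits give the equipotent doses Dx1, Dx2.
    """
    if not (0.0 < x < 1.0):
        raise InputError(f"effect level x must be in (0,1), got {x}")
    for name, fit in (("agent 1", single1), ("agent 2", single2)):
        if not fit.valid:
            raise FitError(f"invalid single-agent median-effect fit for {name}")
    if mixture_fit is None:
        mixture_fit = fit_median_effect(mixture.as_dose_effect())
    if not mixture_fit.valid:
        raise FitError("invalid mixture median-effect fit")

    d_total = dose_at_effect(mixture_fit, x)
    d1 = mixture.fraction1 * d_total
    d2 = (1.0 - mixture.fraction1) * d_total
    dx1 = dose_at_effect(single1, x)
    dx2 = dose_at_effect(single2, x)
    ci = d1 / dx1 + d2 / dx2
    return CombinationResult(
        agent1=mixture.agent1, agent2=mixture.agent2, ratio=mixture.ratio, x=x,
        dx1=dx1, dx2=dx2, d1=d1, d2=d2, ci=float(ci),
        dri1=float(dx1 / d1), dri2=float(dx2 / d2),
        label=classify_interaction(float(ci)),
    )


def isobologram_points(results: list[CombinationResult]) -> pd.DataFrame:
    """Dose-normalised isobologram coordinates (d1/Dx1, d2/Dx2) per result."""
    if not results:
        raise InputError("no combination results to plot")
    rows = []
    for r in results:
        u, v = r.isobole_point
        rows.append({"agent1": r.agent1, "agent2": r.agent2,
                     "ratio": f"{r.ratio[0]}:{r.ratio[1]}", "x": r.x,
                     "u": u, "v": v, "ci": r.ci, "label": r.label})
    return pd.DataFrame(rows)


def _resample(df: pd.DataFrame, dose_col: str, rng) -> pd.DataFrame:
    parts = []
    for _, grp in df.groupby(dose_col, sort=False):
        idx = rng.integers(0, len(grp), len(grp))
        parts.append(grp.iloc[idx])
    return pd.concat(parts, ignore_index=True)


def _group_size_correction(sizes) -> float:
    """Finite-sample rescaling for within-group resampling.

    Resampling n items with replacement underestimates the group variance
    by (n-1)/n; the SD is rescaled by sqrt(nbar/(nbar-1)) with nbar the
    mean replicates per dose.
    """
    nbar = float(np.mean(sizes))
    return float(np.sqrt(nbar / (nbar - 1.0)))


def ci_bootstrap(series1: DoseEffectSeries, series2: DoseEffectSeries,
                 mixture: MixtureSeries, x: float = 0.5, n_boot: int = 1000,
                 seed: int = 0) -> float:
    """Bootstrap SD of the combination index.

    Replicates are resampled with replacement within each dose of the two
    single-agent series and the mixture; all three curves are refitted and
    CI recomputed per resample.  Requires >=2 replicates per dose.
    """
    if n_boot < 50:
        warnings.warn(f"n_boot={n_boot} is small; SD will be unstable", stacklevel=2)
    for s in (series1, series2):
        if s.data.groupby("dose_mM")["replicate"].count().min() < 2:
            raise BootstrapError("bootstrap needs >=2 replicates per dose (single agent)")
    if mixture.data.groupby("dose_total_mM")["replicate"].count().min() < 2:
        raise BootstrapError("bootstrap needs >=2 replicates per dose (mixture)")

    rng = np.random.default_rng(seed)
    vals = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-resample fit warnings are expected
        for _ in range(n_boot):
            try:
                f1 = fit_median_effect(_resample(series1.data, "dose_mM", rng))
                f2 = fit_median_effect(_resample(series2.data, "dose_mM", rng))
                mix = MixtureSeries(agent1=mixture.agent1, agent2=mixture.agent2,
                                    ratio=mixture.ratio, fraction1=mixture.fraction1,
                                    data=_resample(mixture.data, "dose_total_mM", rng),
                                    role=mixture.role)
                res = combination_index(f1, f2, mix, x)
            except (FitError, InputError):
                continue
            vals.append(res.ci)
    if len(vals) < 2:
        raise BootstrapError("too few successful bootstrap resamples")
    sizes = pd.concat([
        series1.data.groupby("dose_mM")["replicate"].count(),
        series2.data.groupby("dose_mM")["replicate"].count(),
        mixture.data.groupby("dose_total_mM")["replicate"].count(),
    ])
    return float(np.std(vals, ddof=1) * _group_size_correction(sizes))


def combination_report(results: list[CombinationResult]) -> pd.DataFrame:
    """Tabular report: one row per (ratio, x) plus a mean-CI summary row."""
    rows = []
    for r in results:
        rows.append({"agent1": r.agent1, "agent2": r.agent2,
                     "ratio": f"{r.ratio[0]}:{r.ratio[1]}", "x": r.x, "ci": r.ci,
                     "ci_sd": r.ci_sd if r.ci_sd is not None else np.nan,
                     "dri1": r.dri1, "dri2": r.dri2, "label": r.label})
    df = pd.DataFrame(rows)
    if len(df) > 1:
        mean_ci = float(df["ci"].mean())
        summary = {"agent1": df["agent1"].iloc[0], "agent2": df["agent2"].iloc[0],
                   "ratio": "mean", "x": np.nan, "ci": mean_ci, "ci_sd": np.nan,
                   "dri1": np.nan, "dri2": np.nan,
                   "label": classify_interaction(mean_ci)}
        df = pd.concat([df, pd.DataFrame([summary])], ignore_index=True)
    return df
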