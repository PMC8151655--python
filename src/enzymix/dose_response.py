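"""Dose-effect analysis: effect fractions, the median-effect model, EC50s.

Rates become effect fractions fa according to the assay role:

* inhibition   fa = 1 - v/v0          (v0 = no-effector control rate)
* scavenging   fa = (A_blank - A)/A_blank   (endpoint decolorisation)
* activation   activation% = 100.(v/v0 - 1); the fraction used for
  median-effect work is activation% normalised by the fitted plateau of the
  hyperbolic dose-activation curve, so fa stays inside (0, 1) even when the
  effector more than doubles Vmax.

The median-effect law fa/(1-fa) = (D/Dm)^m is fitted by OLS on
log10(fa/(1-fa)) against log10(D) (slope m, Dm = 10^(-intercept/m)); the
equipotent dose at effect x is Dx = Dm.(x/(1-x))^(1/m).  AC50 for
activation is the dose at which the *un-normalised* activation curve
reaches 50% activation; IC50 for inhibition/scavenging coincides with Dm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import (
    BootstrapError,
    DataQualityError,
    FitError,
    InputError,
    InsufficientDataError,
)

ROLES = ("activation", "inhibition", "scavenging")
DEFAULT_FA_BOUNDS = (0.01, 0.99)


@dataclass
class DoseEffectSeries:
    """Per-replicate effect fractions of one agent at positive doses.

    ``data`` columns: ``dose_mM``, ``replicate``, ``fa`` and, for
    activation, ``activation_pct``.
    """

    agent: str
    role: str
    data: pd.DataFrame
    control_rate: float | None = None
    plateau_pct: float | None = None   # fitted 100.Emax, activation only

    def __post_init__(self):
        if self.role not in ROLES:
            raise InputError(f"role must be one of {ROLES}, got {self.role!r}")
        need = {"dose_mM", "replicate", "fa"}
        if need - set(self.data.columns):
            raise InputError(f"dose-effect data needs columns {sorted(need)}")
        if (self.data["dose_mM"] <= 0).any():
            raise InputError("dose-effect doses must be strictly positive")

    @property
    def doses(self) -> np.ndarray:
        return np.sort(self.data["dose_mM"].unique())


def hyperbolic_activation_pct(dose, ka, emax):
    """Percent activation of the nonessential-activator model: 100.Emax.A/(Ka+A)."""
    dose = np.asarray(dose, dtype=float)
    return 100.0 * emax * dose / (ka + dose)


def fit_activation_plateau(doses, activation_pct, rng=None) -> tuple[float, float]:
    """Fit (Ka, Emax) of the hyperbolic dose-activation curve by NLS."""
    d = np.asarray(doses, dtype=float)
    a = np.asarray(activation_pct, dtype=float)
    if np.unique(d).size < 3:
        raise InsufficientDataError("need >=3 distinct doses for the activation fit")
    emax0 = max(a.max() / 100.0, 0.05)
    ka0 = float(np.median(d))
    rng = np.random.default_rng(0) if rng is None else rng

    def resid(theta):
        ka, emax = np.exp(theta)
        return hyperbolic_activation_pct(d, ka, emax) - a

    best = None
    theta0 = np.log([ka0, emax0])
    for attempt in range(5):
        t0 = theta0 if attempt == 0 else theta0 + rng.normal(0, 0.5, 2)
        try:
            sol = least_squares(resid, t0, method="lm", xtol=1e-14, ftol=1e-14)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
        if attempt == 0 and sol.success:
            break
    if best is None:
        raise FitError("activation plateau fit failed")
    ka, emax = np.exp(best.x)
    return float(ka), float(emax)


def effect_fraction(rates: pd.DataFrame, role: str, control_rate: float | None = None,
                    plateau_pct: float | None = None, agent: str | None = None,
                    fa_bounds: tuple[float, float] = DEFAULT_FA_BOUNDS) -> DoseEffectSeries:
    """Convert a rates table to a :class:`DoseEffectSeries`.

    ``rates`` needs columns ``dose_mM``, ``replicate`` and ``rate`` (for
    scavenging, ``rate`` holds the endpoint absorbance and the control is
    the blank read).  The control defaults to the mean of dose-0 rows.
    Raises :class:`DataQualityError` when more than half of the points fall
    outside the fa clipping bounds.
    """
    if role not in ROLES:
        raise InputError(f"role must be one of {ROLES}, got {role!r}")
    df = rates.copy()
    df["dose_mM"] = df["dose_mM"].fillna(0.0)
    if control_rate is None:
        ctrl = df.loc[df["dose_mM"] == 0, "rate"]
        if ctrl.empty:
            raise InputError("no dose-0 control rows and no control_rate given")
        control_rate = float(ctrl.mean())
    if control_rate <= 0:
        raise InputError(f"control rate must be positive, got {control_rate}")

    dosed = df[df["dose_mM"] > 0].copy()
    if role in ("inhibition", "scavenging"):
        dosed["fa"] = 1.0 - dosed["rate"] / control_rate
    else:
        dosed["activation_pct"] = 100.0 * (dosed["rate"] / control_rate - 1.0)
        if plateau_pct is None:
            ka, emax = fit_activation_plateau(dosed["dose_mM"], dosed["activation_pct"])
            plateau_pct = 100.0 * emax
        dosed["fa"] = dosed["activation_pct"] / plateau_pct

    lo, hi = fa_bounds
    outside = (dosed["fa"] < lo) | (dosed["fa"] > hi)
    if outside.sum() > 0.5 * len(dosed):
        raise DataQualityError(
            f"{int(outside.sum())}/{len(dosed)} effect fractions outside [{lo}, {hi}]"
        )
    cols = ["dose_mM", "replicate", "fa"] + (["activation_pct"] if role == "activation" else [])
    return DoseEffectSeries(agent=agent or str(df.get("compound", pd.Series([""])).iloc[0]),
                            role=role, data=dosed[cols].reset_index(drop=True),
                            control_rate=control_rate, plateau_pct=plateau_pct)


@dataclass
class MedianEffectFit:
    """Median-effect parameters: Dm (dose at fa=0.5), sigmoidicity m."""

    dm: float
    m: float
    r: float
    cov_logdm_m: np.ndarray = field(default_factory=lambda: np.full((2, 2), np.nan))
    n: int = 0
    valid: bool = True


def fit_median_effect(series, fa_bounds: tuple[float, float] = DEFAULT_FA_BOUNDS
                      ) -> MedianEffectFit:
    """OLS fit of the median-effect transform on per-replicate points.

    fa values at exactly 0 or 1 are excluded with a warning; the rest are
    clipped to ``fa_bounds`` before the logit-log transform.  A fit whose
    slope m is non-positive is returned with ``valid=False``.
    """
    if isinstance(series, DoseEffectSeries):
        df = series.data
    else:
        df = series
    d = df["dose_mM"].to_numpy(dtype=float)
    fa = df["fa"].to_numpy(dtype=float)
    keep = (fa > 0.0) & (fa < 1.0)
    if not keep.all():
        warnings.warn(f"excluding {np.count_nonzero(~keep)} point(s) with fa at 0 or 1",
                      stacklevel=2)
    d, fa = d[keep], fa[keep]
    if np.unique(d).size < 3:
        raise InsufficientDataError("median-effect fit needs >=3 usable doses")
    fa = np.clip(fa, *fa_bounds)

    x = np.log10(d)
    y = np.log10(fa / (1.0 - fa))
    (m, b), cov_bm = _polyfit_cov(x, y)
    r = float(np.corrcoef(x, y)[0, 1]) if np.std(y) > 0 else 1.0
    valid = m > 0
    dm = 10.0 ** (-b / m) if valid else float("nan")
    # delta method: log10(Dm) = -b/m
    if valid and np.all(np.isfinite(cov_bm)):
        J = np.array([[-1.0 / m, b / m ** 2], [0.0, 1.0]])  # rows: (logDm, m); cols: (b, m)
        cov = J @ cov_bm @ J.T
    else:
        cov = np.full((2, 2), np.nan)
    return MedianEffectFit(dm=float(dm), m=float(m), r=r, cov_logdm_m=cov,
                           n=int(d.size), valid=bool(valid))


def _polyfit_cov(x, y):
    """Slope/intercept OLS with covariance; exact-fit covariance is zero."""
    n = x.size
    X = np.column_stack([x, np.ones_like(x)])
    beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
    m, b = beta
    pred = X @ beta
    rss = float(np.sum((y - pred) ** 2))
    dof = max(n - 2, 1)
    sigma2 = rss / dof
    try:
        cov_mb = sigma2 * np.linalg.inv(X.T @ X)  # order (m, b)
        cov_bm = cov_mb[::-1, ::-1]
    except np.linalg.LinAlgError:
        cov_bm = np.full((2, 2), np.nan)
    return (float(m), float(b)), cov_bm


def dose_at_effect(fit: MedianEffectFit, x: float) -> float:
    """Equipotent dose Dx = Dm.(x/(1-x))^(1/m) producing effect fraction x."""
    if not (0.0 < x < 1.0):
        raise InputError(f"effect fraction must lie in (0, 1), got {x}")
    if not fit.valid:
        raise FitError("cannot evaluate Dx on an invalid median-effect fit")
    return float(fit.dm * (x / (1.0 - x)) ** (1.0 / fit.m))


def effect_at_dose(fit: MedianEffectFit, dose: float) -> float:
    """Inverse of :func:`dose_at_effect`: fa = (D/Dm)^m / (1 + (D/Dm)^m)."""
    if dose <= 0:
        raise InputError("dose must be positive")
    if not fit.valid:
        raise FitError("cannot evaluate an invalid median-effect fit")
    q = (dose / fit.dm) ** fit.m
    return float(q / (1.0 + q))


@dataclass
class Ec50Result:
    value: float
    sd: float
    n_boot: int
    role: str
    fit: MedianEffectFit | None = None
    ka: float | None = None
    emax: float | None = None


def _resample_within_dose(df: pd.DataFrame, rng) -> pd.DataFrame:
    parts = []
    for _, grp in df.groupby("dose_mM", sort=False):
        idx = rng.integers(0, len(grp), len(grp))
        parts.append(grp.iloc[idx])
    return pd.concat(parts, ignore_index=True)


def _ec50_point(series: DoseEffectSeries, df: pd.DataFrame) -> tuple[float, dict]:
    if series.role == "activation":
        ka, emax = fit_activation_plateau(df["dose_mM"], df["activation_pct"])
        if emax <= 0.5:
            raise FitError("activation plateau below 50%: AC50 undefined")
        # 100.Emax.A/(Ka+A) = 50  =>  A = Ka / (2.Emax - 1)
        return ka / (2.0 * emax - 1.0), {"ka": ka, "emax": emax}
    fit = fit_median_effect(df)
    if not fit.valid:
        raise FitError("invalid median-effect fit (non-positive slope)")
    return fit.dm, {"fit": fit}


def estimate_ec50(series: DoseEffectSeries, n_boot: int = 1000, seed: int = 0) -> Ec50Result:
    """EC50 point estimate with a nonparametric bootstrap SD.

    Inhibition/scavenging report IC50 = Dm of the median-effect fit;
    activation reports the AC50 at which the un-normalised hyperbolic
    dose-activation curve predicts 50% activation.  The bootstrap resamples
    replicates within each dose.
    """
    point, extra = _ec50_point(series, series.data)
    rng = np.random.default_rng(seed)
    vals = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-resample fit warnings are expected
        for _ in range(n_boot):
            df = _resample_within_dose(series.data, rng)
            try:
                v, _ = _ec50_point(series, df)
            except (FitError, InsufficientDataError):
                continue
            vals.append(v)
    if len(vals) > 1:
        # finite-sample rescaling: within-group resampling of n replicates
        # underestimates the group variance by (n-1)/n
        nbar = float(series.data.groupby("dose_mM")["replicate"].count().mean())
        factor = np.sqrt(nbar / (nbar - 1.0)) if nbar > 1 else 1.0
        sd = float(np.std(vals, ddof=1) * factor)
    else:
        sd = 0.0
    return Ec50Result(value=float(point), sd=sd, n_boot=len(vals), role=series.role,
                      fit=extra.get("fit"), ka=extra.get("ka"), emax=extra.get("emax"))


def bootstrap_fits(series: DoseEffectSeries, n_boot: int, rng) -> list[MedianEffectFit]:
    """Median-effect fits over within-dose replicate resamples (internal)."""
    if series.data.groupby("dose_mM")["replicate"].count().min() < 2:
        raise BootstrapError("bootstrap needs >=2 replicates per dose")
    out = []
    for _ in range(n_boot):
        try:
            out.append(fit_median_effect(_resample_within_dose(series.data, rng)))
        except (FitError, InsufficientDataError):
            out.append(None)
    return out
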