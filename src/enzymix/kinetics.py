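"""Michaelis-Menten kinetics across effector doses and mechanism calls.

An effector (inhibitor or activator) is characterised by fitting five
candidate rapid-equilibrium global models to the complete substrate x
effector-dose x replicate rate grid, all sharing one control (Km, Vmax):

* ``none``           v = Vmax.S/(Km + S)
* ``competitive``    apparent Km = Km.(1 + I/Ki)
* ``uncompetitive``  apparent Km and Vmax both divided by (1 + I/Ki)
* ``noncompetitive`` apparent Vmax = Vmax/(1 + I/Ki)
* ``mixed``          Km scaled by (1 + I/Kic), Vmax by 1/(1 + I/Kiu)
* ``activation``     Vmax multiplied by (1 + Emax.A/(Ka + A))

Candidates are compared by small-sample corrected AIC (AICc); ties within
two AICc units go to the model with fewer parameters.  Parameters are
estimated by nonlinear least squares on untransformed rates; the
Lineweaver-Burk double-reciprocal line is produced for display only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import ClassificationError, FitError, InputError, InsufficientDataError

MECHANISMS = ("none", "competitive", "uncompetitive", "noncompetitive", "mixed", "activation")


@dataclass
class EffectorKineticSeries:
    """Substrate-velocity grids at several effector doses, control included.

    ``data`` is long format with columns ``dose_mM``, ``substrate_mM``,
    ``replicate``, ``rate``.  Dose 0 is the no-effector control block.
    """

    effector: str
    data: pd.DataFrame

    def __post_init__(self):
        need = {"dose_mM", "substrate_mM", "replicate", "rate"}
        missing = need - set(self.data.columns)
        if missing:
            raise InputError(f"kinetic series missing columns: {sorted(missing)}")
        doses = self.doses
        if (doses < 0).any():
            raise InputError("effector doses must be >= 0")
        if 0.0 not in doses:
            raise InputError("control block (dose 0) is required")
        for d, grp in self.data.groupby("dose_mM"):
            if grp["substrate_mM"].nunique() < 4:
                raise InsufficientDataError(
                    f"dose {d}: needs >=4 distinct substrate concentrations"
                )

    @property
    def doses(self) -> np.ndarray:
        return np.sort(self.data["dose_mM"].unique())

    def block(self, dose: float) -> pd.DataFrame:
        return self.data[self.data["dose_mM"] == dose]


def series_from_rates(rates: pd.DataFrame, effector: str | None = None) -> EffectorKineticSeries:
    """Build a kinetic series from a rates table (as read by plate_io)."""
    df = rates.copy()
    if effector is not None and "compound" in df.columns:
        mask = (df["compound"] == effector) | df["dose_mM"].fillna(0).eq(0)
        df = df[mask]
    df = df.rename(columns={"rate": "rate"})
    df["dose_mM"] = df["dose_mM"].fillna(0.0)
    out = df[["dose_mM", "substrate_mM", "replicate", "rate"]].copy()
    return EffectorKineticSeries(effector=effector or "", data=out)


@dataclass
class MMFit:
    km: float
    vmax: float
    km_se: float
    vmax_se: float
    residual_sd: float
    n: int


def michaelis_menten(s, km, vmax):
    s = np.asarray(s, dtype=float)
    return vmax * s / (km + s)


def fit_michaelis_menten(block, n_restarts: int = 5, rng=None) -> MMFit:
    """Nonlinear least-squares (Km, Vmax) fit of one substrate-rate block.

    ``block`` is a DataFrame with ``substrate_mM``/``rate`` columns or a
    pair of arrays.  Initialisation: Vmax0 = max rate, Km0 = substrate at
    half-max; up to ``n_restarts`` jittered restarts on failure.
    """
    if isinstance(block, pd.DataFrame):
        s = block["substrate_mM"].to_numpy(dtype=float)
        v = block["rate"].to_numpy(dtype=float)
    else:
        s, v = (np.asarray(a, dtype=float) for a in block)
    if np.unique(s).size < 4:
        raise InsufficientDataError("need >=4 distinct substrate concentrations")
    if np.any(s <= 0):
        raise InputError("substrate concentrations must be positive")
    if np.any(v <= 0):
        raise InputError("rates must be positive for Michaelis-Menten fitting")

    vmax0 = float(v.max())
    km0 = _half_max_substrate(s, v)
    rng = np.random.default_rng(0) if rng is None else rng

    def resid(theta):
        km, vmax = np.exp(theta)
        return michaelis_menten(s, km, vmax) - v

    best = None
    theta0 = np.log([km0, vmax0])
    for attempt in range(n_restarts + 1):
        t0 = theta0 if attempt == 0 else theta0 + rng.normal(0, 0.5, 2)
        try:
            sol = least_squares(resid, t0, method="lm", xtol=1e-14, ftol=1e-14)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
        if sol.success and attempt == 0:
            break
    if best is None:
        raise FitError("Michaelis-Menten fit failed to converge")

    km, vmax = np.exp(best.x)
    r = best.fun
    n, p = v.size, 2
    dof = max(n - p, 1)
    sigma2 = float(r @ r) / dof
    # delta-method SEs from the log-parameter Jacobian
    J = best.jac
    try:
        cov_log = sigma2 * np.linalg.inv(J.T @ J)
        km_se = float(np.sqrt(cov_log[0, 0]) * km)
        vmax_se = float(np.sqrt(cov_log[1, 1]) * vmax)
    except np.linalg.LinAlgError:
        km_se = vmax_se = float("nan")
    return MMFit(km=float(km), vmax=float(vmax), km_se=km_se, vmax_se=vmax_se,
                 residual_sd=float(np.sqrt(sigma2)), n=n)


def _half_max_substrate(s, v) -> float:
    half = v.max() / 2.0
    idx = int(np.argmin(np.abs(v - half)))
    return max(float(s[idx]), 1e-12)


@dataclass
class LineweaverBurk:
    """Double-reciprocal coordinates and OLS line (display/diagnostics only)."""

    inv_s: np.ndarray
    inv_v: np.ndarray
    slope: float       # = Km_app / Vmax_app
    intercept: float   # = 1 / Vmax_app


def lineweaver_burk(block) -> LineweaverBurk:
    if isinstance(block, pd.DataFrame):
        s = block["substrate_mM"].to_numpy(dtype=float)
        v = block["rate"].to_numpy(dtype=float)
    else:
        s, v = (np.asarray(a, dtype=float) for a in block)
    if np.any(s <= 0):
        raise InputError("substrate concentrations must be positive")
    keep = v > 0
    if not keep.all():
        warnings.warn(f"excluding {np.count_nonzero(~keep)} non-positive rate(s) "
                      "from Lineweaver-Burk plot", stacklevel=2)
    s, v = s[keep], v[keep]
    if s.size < 2:
        raise InsufficientDataError("need >=2 positive-rate points for a reciprocal line")
    x, y = 1.0 / s, 1.0 / v
    slope, intercept = np.polyfit(x, y, 1)
    return LineweaverBurk(inv_s=x, inv_v=y, slope=float(slope), intercept=float(intercept))


# ---------------------------------------------------------------------------
# global mechanism models

_N_PARAMS = {"none": 2, "competitive": 3, "uncompetitive": 3,
             "noncompetitive": 3, "mixed": 4, "activation": 4}


def _predict(name: str, params: np.ndarray, s: np.ndarray, d: np.ndarray) -> np.ndarray:
    km, vmax = params[0], params[1]
    if name == "none":
        return vmax * s / (km + s)
    if name == "competitive":
        ki = params[2]
        return vmax * s / (km * (1 + d / ki) + s)
    if name == "uncompetitive":
        ki = params[2]
        return vmax * s / (km + s * (1 + d / ki))
    if name == "noncompetitive":
        ki = params[2]
        return (vmax / (1 + d / ki)) * s / (km + s)
    if name == "mixed":
        kic, kiu = params[2], params[3]
        return vmax * s / (km * (1 + d / kic) + s * (1 + d / kiu))
    if name == "activation":
        ka, emax = params[2], params[3]
        return vmax * (1 + emax * d / (ka + d)) * s / (km + s)
    raise InputError(f"unknown mechanism {name!r}")


def apparent_parameters(name: str, params: np.ndarray, dose: float) -> tuple[float, float]:
    """Apparent (Km, Vmax) of a fitted mechanism model at one effector dose."""
    km, vmax = params[0], params[1]
    d = dose
    if name == "none":
        return km, vmax
    if name == "competitive":
        return km * (1 + d / params[2]), vmax
    if name == "uncompetitive":
        f = 1 + d / params[2]
        return km / f, vmax / f
    if name == "noncompetitive":
        return km, vmax / (1 + d / params[2])
    if name == "mixed":
        kic, kiu = params[2], params[3]
        return km * (1 + d / kic) / (1 + d / kiu), vmax / (1 + d / kiu)
    if name == "activation":
        ka, emax = params[2], params[3]
        return km, vmax * (1 + emax * d / (ka + d))
    raise InputError(f"unknown mechanism {name!r}")


@dataclass
class MechanismCall:
    """Winning mechanism with its global parameters and per-candidate scores."""

    label: str
    km: float
    vmax: float
    ki: float | None            # Ki (inhibition) or Ka (activation)
    emax: float | None          # activation plateau fold-increase, if applicable
    per_dose: pd.DataFrame      # dose_mM, km_app, vmax_app
    scores: dict[str, float]    # AICc per candidate
    params: dict[str, np.ndarray] = field(default_factory=dict, repr=False)


def _fit_global(name, s, d, v, km0, vmax0, ki0, rng, n_restarts=4):
    p = _N_PARAMS[name]
    if name == "none":
        theta0 = np.log([km0, vmax0])
    elif name == "mixed":
        theta0 = np.log([km0, vmax0, ki0, ki0])
    elif name == "activation":
        ctrl = v[d == 0].mean()
        emax0 = max(v[d > 0].mean() / max(ctrl, 1e-12) - 1.0, 0.1)
        theta0 = np.log([km0, vmax0, ki0, emax0])
    else:
        theta0 = np.log([km0, vmax0, ki0])

    def resid(theta):
        return _predict(name, np.exp(theta), s, d) - v

    best = None
    for attempt in range(n_restarts + 1):
        t0 = theta0 if attempt == 0 else theta0 + rng.normal(0, 0.7, p)
        try:
            sol = least_squares(resid, t0, method="lm", xtol=1e-14, ftol=1e-14)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
        if attempt == 0 and sol.success:
            break
    if best is None:
        return None, np.inf
    return np.exp(best.x), 2.0 * best.cost  # rss


def _aicc(rss, n, p):
    k = p + 1  # + residual variance
    if n - k - 1 <= 0:
        return np.inf
    return n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _component_effects(name: str, params: np.ndarray, s: np.ndarray,
                       dmax: float) -> list[float]:
    """Maximal fractional rate change each effector component produces.

    Evaluated at the largest tested dose over the observed substrate grid;
    a component is 'switched off' by sending its constant to infinity
    (or Emax to 0 for activation).  ``none`` has no components.
    """
    ss = np.unique(s)
    dd = np.full_like(ss, dmax)
    full = _predict(name, params, ss, dd)

    def rel_effect(reduced):
        return float(np.max(np.abs(reduced - full) / full))

    if name == "none":
        return []
    if name in ("competitive", "uncompetitive", "noncompetitive"):
        off = params.copy()
        off[2] = np.inf
        return [rel_effect(_predict(name, off, ss, dd))]
    if name == "mixed":
        effs = []
        for idx in (2, 3):  # kic, kiu
            off = params.copy()
            off[idx] = np.inf
            effs.append(rel_effect(_predict(name, off, ss, dd)))
        return effs
    if name == "activation":
        off = params.copy()
        off[3] = 0.0
        return [rel_effect(_predict(name, off, ss, dd))]
    raise InputError(f"unknown mechanism {name!r}")


def classify_mechanism(series: EffectorKineticSeries,
                       candidates: tuple[str, ...] = MECHANISMS,
                       aicc_tie: float = 2.0,
                       resolvability: float = 2.0,
                       seed: int = 0) -> MechanismCall:
    """Fit the candidate global models and call the effector mechanism.

    Selection is by AICc; any candidate within ``aicc_tie`` units of the
    minimum is eligible and the one with fewest parameters wins (simpler
    model on ties).  Candidates whose fitted effector components are not
    identifiable are screened out first: every component must change
    predicted rates at the largest tested dose by more than
    ``resolvability`` times the residual coefficient of variation of the
    best fit, otherwise the model has collapsed onto a simpler nested law
    and the simpler candidate is reported instead.  ``activation`` is only
    called when the fitted rates exceed the control at every nonzero dose.
    """
    doses = series.doses
    if np.count_nonzero(doses > 0) < 2:
        raise ClassificationError("need control plus >=2 nonzero effector doses")

    s = series.data["substrate_mM"].to_numpy(dtype=float)
    d = series.data["dose_mM"].to_numpy(dtype=float)
    v = series.data["rate"].to_numpy(dtype=float)
    n = v.size
    rng = np.random.default_rng(seed)

    ctrl_fit = fit_michaelis_menten(series.block(0.0), rng=rng)
    km0, vmax0 = ctrl_fit.km, ctrl_fit.vmax
    ki0 = float(np.median(doses[doses > 0]))

    tss = float(np.sum((v - v.mean()) ** 2))
    rss_floor = max(tss, 1.0) * 1e-18  # keeps AICc finite & scale-invariant

    scores, params, rss_map = {}, {}, {}
    for name in candidates:
        est, rss = _fit_global(name, s, d, v, km0, vmax0, ki0, rng)
        if est is None:
            scores[name] = np.inf
            continue
        params[name] = est
        rss_map[name] = rss
        scores[name] = _aicc(max(rss, rss_floor), n, _N_PARAMS[name])

    if not params:
        raise ClassificationError("all candidate model fits failed")

    # identifiability screen: every effector component of a candidate must be
    # resolvable above the noise level of the best fit at the top dose
    noise_cv_hat = float(np.sqrt(min(rss_map.values()) / n) / np.mean(v))
    dmax = float(doses.max())
    tol = resolvability * noise_cv_hat
    admissible = {m for m in params
                  if all(e > tol for e in _component_effects(m, params[m], s, dmax))}
    if not admissible:
        admissible = set(params)

    order = sorted(admissible, key=lambda m: scores[m])
    best_score = scores[order[0]]
    eligible = [m for m in order if scores[m] - best_score < aicc_tie]
    eligible.sort(key=lambda m: (_N_PARAMS[m], scores[m]))

    label = None
    for cand in eligible + [m for m in order if m not in eligible]:
        if cand == "activation" and not _rates_above_control(params[cand], s, d):
            continue
        label = cand
        break
    if label is None:
        raise ClassificationError("no admissible mechanism model")

    est = params[label]
    per_dose = pd.DataFrame(
        [{"dose_mM": dd, **dict(zip(("km_app", "vmax_app"),
                                    apparent_parameters(label, est, dd)))}
         for dd in doses]
    )
    ki = float(est[2]) if label not in ("none",) else None
    emax = float(est[3]) if label == "activation" else None
    return MechanismCall(label=label, km=float(est[0]), vmax=float(est[1]),
                         ki=ki, emax=emax, per_dose=per_dose, scores=scores,
                         params=params)


def _rates_above_control(params, s, d) -> bool:
    """Fitted activation rates must exceed control at every nonzero dose."""
    for dd in np.unique(d[d > 0]):
        ss = np.unique(s[d == dd])
        if not np.all(_predict("activation", params, ss, np.full_like(ss, dd))
                      > _predict("activation", params, ss, np.zeros_like(ss))):
            return False
    return True


def kinetics_report(call: MechanismCall, effector: str) -> pd.DataFrame:
    """One row per dose (apparent parameters) plus a summary row."""
    rows = call.per_dose.copy()
    rows.insert(0, "effector", effector)
    rows["label"] = ""
    rows["ki"] = np.nan
    summary = pd.DataFrame([{
        "effector": effector, "dose_mM": np.nan,
        "km_app": call.km, "vmax_app": call.vmax,
        "label": call.label, "ki": call.ki if call.ki is not None else np.nan,
    }])
    return pd.concat([rows, summary], ignore_index=True)
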