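"""Synthetic assay data with known ground truth.

Emulates the three assay families the pipeline analyses so that every
downstream stage can be verified by parameter recovery:

* peroxidase-type activation kinetics (guaiacol oxidation followed at
  470 nm) with a hyperbolic Vmax multiplier,
* lipoxygenase-type inhibition kinetics (linoleate conjugated dienes at
  234 nm) under competitive / uncompetitive / noncompetitive laws,
* radical-scavenging style endpoint dose-effect reads, and
* fixed-ratio two-agent mixtures (default volume ratios 1:4, 4:1, 3:2,
  2:3, 1:1) constructed with a controllable Loewe interaction index psi:
  at every target effect x the total mixture dose solves
  d1/Dx1(x) + d2/Dx2(x) = psi, so an ideal analysis recovers CI = psi.

Noise is multiplicative Gaussian on rates (coefficient of variation
``noise_cv``, truncated at -0.99 so rates stay positive), matching the
roughly proportional error of plate readers.  All draws flow from
``numpy.random.default_rng(seed)``: identical truths and seeds give
bit-identical datasets.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .combination import MixtureSeries, ratio_fractions
from .dose_response import DoseEffectSeries, MedianEffectFit, dose_at_effect
from .errors import InputError
from .kinetics import EffectorKineticSeries
from .plate_io import KineticTrace, SampleAnnotation

MECHANISMS = ("none", "competitive", "uncompetitive", "noncompetitive", "activation")
DEFAULT_RATIOS = ((1, 4), (4, 1), (3, 2), (2, 3), (1, 1))


@dataclass(frozen=True)
class KineticTruth:
    """Ground-truth enzyme/effector parameters for kinetic-series simulation.

    ``k_effector`` is Ki for inhibition mechanisms and Ka (half-saturating
    activator dose) for activation; ``activation_emax`` is the plateau
    fold-increase of Vmax (activation only).
    """

    km: float
    vmax: float
    mechanism: str = "none"
    k_effector: float | None = None
    activation_emax: float | None = None
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.km <= 0:
            raise InputError(f"Km must be positive, got {self.km}")
        if self.vmax <= 0:
            raise InputError(f"Vmax must be positive, got {self.vmax}")
        if self.mechanism not in MECHANISMS:
            raise InputError(f"mechanism must be one of {MECHANISMS}")
        if self.mechanism != "none" and (self.k_effector is None or self.k_effector <= 0):
            raise InputError("k_effector must be positive when mechanism != 'none'")
        if self.mechanism == "activation" and (
                self.activation_emax is None or self.activation_emax <= 0):
            raise InputError("activation requires activation_emax > 0")
        if self.noise_cv < 0:
            raise InputError("noise_cv must be >= 0")


def kinetic_rate(truth: KineticTruth, substrate, dose=0.0) -> np.ndarray:
    """Noise-free rate of the truth model at given substrate and effector dose."""
    s = np.asarray(substrate, dtype=float)
    d = np.asarray(dose, dtype=float)
    km, vmax = truth.km, truth.vmax
    if truth.mechanism == "none":
        return vmax * s / (km + s)
    k = truth.k_effector
    if truth.mechanism == "competitive":
        return vmax * s / (km * (1 + d / k) + s)
    if truth.mechanism == "uncompetitive":
        return vmax * s / (km + s * (1 + d / k))
    if truth.mechanism == "noncompetitive":
        return (vmax / (1 + d / k)) * s / (km + s)
    # activation: hyperbolic Vmax multiplier (nonessential activator)
    return vmax * (1 + truth.activation_emax * d / (k + d)) * s / (km + s)


def default_substrate_grid(km: float, n: int = 8) -> np.ndarray:
    """Log-spaced substrate grid spanning 0.2x to 20x Km."""
    return np.geomspace(0.2 * km, 20.0 * km, n)


def _apply_noise(values: np.ndarray, noise_cv: float, rng) -> np.ndarray:
    if noise_cv == 0:
        return values.copy()
    eps = np.maximum(rng.normal(0.0, noise_cv, size=values.shape), -0.99)
    return values * (1.0 + eps)


def generate_kinetic_series(truth: KineticTruth, effector_doses,
                            substrate_grid=None, replicates: int = 3,
                            effector: str = "effector") -> EffectorKineticSeries:
    """Simulate a substrate x effector-dose x replicate rate grid.

    A dose-0 control block is always present (prepended if absent).  Rates
    are model value x (1 + eps) with eps ~ Normal(0, noise_cv) truncated
    at -0.99.
    """
    doses = np.asarray(effector_doses, dtype=float)
    if doses.size == 0:
        raise InputError("effector dose grid must be non-empty")
    if np.any(doses < 0):
        raise InputError("effector doses must be >= 0")
    if 0.0 not in doses:
        doses = np.concatenate([[0.0], doses])
    if substrate_grid is None:
        substrate_grid = default_substrate_grid(truth.km)
    s = np.asarray(substrate_grid, dtype=float)
    if s.size == 0:
        raise InputError("substrate grid must be non-empty")
    if np.any(s <= 0):
        raise InputError("substrate concentrations must be positive")
    if replicates < 1:
        raise InputError("replicates must be >= 1")

    rng = np.random.default_rng(truth.seed)
    rows = []
    for d in doses:
        model = kinetic_rate(truth, s, d)
        for rep in range(1, replicates + 1):
            rates = _apply_noise(model, truth.noise_cv, rng)
            for si, vi in zip(s, rates):
                rows.append({"dose_mM": d, "substrate_mM": si,
                             "replicate": rep, "rate": vi})
    return EffectorKineticSeries(effector=effector, data=pd.DataFrame(rows))


@dataclass(frozen=True)
class MixtureTruth:
    """Ground truth for a fixed-ratio two-agent mixture experiment.

    psi is the Loewe interaction index built into the mixture construction:
    1 gives exact additivity, <1 synergy, >1 antagonism.
    """

    dm1: float
    dm2: float
    m1: float = 1.0
    m2: float = 1.0
    psi: float = 1.0
    ratios: tuple[tuple[int, int], ...] = DEFAULT_RATIOS
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("dm1", "dm2", "m1", "m2", "psi"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")
        if not self.ratios:
            raise InputError("ratios must be non-empty")
        for p, q in self.ratios:
            if p <= 0 or q <= 0:
                raise InputError(f"ratio parts must be positive, got {(p, q)}")
        if self.noise_cv < 0:
            raise InputError("noise_cv must be >= 0")


def _single_fit(dm: float, m: float) -> MedianEffectFit:
    return MedianEffectFit(dm=dm, m=m, r=1.0, n=0, valid=True)


DEFAULT_EFFECT_GRID = tuple(np.round(np.linspace(0.1, 0.9, 9), 10))


def _noisy_fa(fa_model: np.ndarray, noise_cv: float, rng) -> np.ndarray:
    """Noise acts on the residual activity 1-fa, the measured pseudo-rate."""
    v = _apply_noise(1.0 - fa_model, noise_cv, rng)
    return 1.0 - v


def generate_mixture_series(truth: MixtureTruth, effect_grid=DEFAULT_EFFECT_GRID,
                            replicates: int = 3,
                            stocks_mM: tuple[float, float] = (1.0, 1.0),
                            agents: tuple[str, str] = ("agent1", "agent2"),
                            role: str = "inhibition"
                            ) -> tuple[DoseEffectSeries, DoseEffectSeries, list[MixtureSeries]]:
    """Simulate two single-agent dose-effect series and their fixed-ratio mixtures.

    Single-agent doses are placed at the equipotent doses Dx(x) of the
    effect grid.  For each ratio and target effect x the total mixture dose
    D solves f1.D/Dx1(x) + f2.D/Dx2(x) = psi (f_i the component dose
    fractions), so a noise-free run of the combination analysis returns
    CI = psi at every ratio and effect level.
    """
    x_grid = np.asarray(effect_grid, dtype=float)
    if x_grid.size == 0:
        raise InputError("effect grid must be non-empty")
    if np.any((x_grid <= 0) | (x_grid >= 1)):
        raise InputError("effect fractions must lie strictly inside (0, 1)")
    if replicates < 1:
        raise InputError("replicates must be >= 1")

    rng = np.random.default_rng(truth.seed)
    fit1, fit2 = _single_fit(truth.dm1, truth.m1), _single_fit(truth.dm2, truth.m2)

    singles = []
    for agent, fit in zip(agents, (fit1, fit2)):
        rows = []
        for x in x_grid:
            d = dose_at_effect(fit, float(x))
            for rep in range(1, replicates + 1):
                fa = _noisy_fa(np.array([x]), truth.noise_cv, rng)[0]
                rows.append({"dose_mM": d, "replicate": rep, "fa": fa})
        singles.append(DoseEffectSeries(agent=agent, role=role,
                                        data=pd.DataFrame(rows), control_rate=1.0))

    mixtures = []
    for ratio in truth.ratios:
        f1, f2 = ratio_fractions(ratio, stocks_mM)
        rows = []
        for x in x_grid:
            dx1 = dose_at_effect(fit1, float(x))
            dx2 = dose_at_effect(fit2, float(x))
            d_total = truth.psi / (f1 / dx1 + f2 / dx2)
            for rep in range(1, replicates + 1):
                fa = _noisy_fa(np.array([x]), truth.noise_cv, rng)[0]
                rows.append({"dose_total_mM": d_total, "replicate": rep, "fa": fa})
        mixtures.append(MixtureSeries(agent1=agents[0], agent2=agents[1], ratio=ratio,
                                      fraction1=f1, data=pd.DataFrame(rows), role=role))
    return singles[0], singles[1], mixtures


def generate_plate_traces(rate: float, duration_min: float = 3.0, interval_min: float = 1.0,
                          baseline_au: float = 0.1, noise_sd_au: float = 0.0,
                          seed: int = 0, wavelength_nm: float = 470.0,
                          well_id: str = "A1",
                          annotation: SampleAnnotation | None = None) -> KineticTrace:
    """Simulate a linear absorbance trace of the given slope (delta-AU/min)."""
    if interval_min <= 0:
        raise InputError("read interval must be positive")
    if duration_min < 2 * interval_min:
        raise InputError("duration must span at least 2 read intervals")
    if noise_sd_au < 0:
        raise InputError("noise SD must be >= 0")
    n = int(np.floor(duration_min / interval_min + 1e-9)) + 1
    t = np.arange(n) * interval_min
    a = baseline_au + rate * t
    if noise_sd_au > 0:
        a = a + np.random.default_rng(seed).normal(0.0, noise_sd_au, size=n)
    return KineticTrace(well_id=well_id, wavelength_nm=wavelength_nm, times_min=t,
                        absorbances_au=a,
                        annotation=annotation or SampleAnnotation())


# ---------------------------------------------------------------------------
# CSV export in the plate_io rates schema + truth sidecars


def kinetic_series_to_rates(series: EffectorKineticSeries,
                            substrate_name: str = "substrate") -> pd.DataFrame:
    df = series.data.copy()
    return pd.DataFrame({
        "well_id": [f"K{i}" for i in range(len(df))],
        "wavelength_nm": np.nan,
        "compound": np.where(df["dose_mM"] > 0, series.effector, ""),
        "dose_mM": df["dose_mM"], "compound2": "", "dose2_mM": np.nan,
        "substrate_mM": df["substrate_mM"], "ratio": "",
        "replicate": df["replicate"], "rate": df["rate"],
    })


def dose_series_to_rates(series: DoseEffectSeries, control_rate: float = 1.0,
                         replicates_control: int = 3) -> pd.DataFrame:
    """Rates-table encoding of a dose-effect series (pseudo-rate = 1 - fa)."""
    rows = [{"well_id": f"C{r}", "wavelength_nm": np.nan, "compound": "",
             "dose_mM": 0.0, "compound2": "", "dose2_mM": np.nan,
             "substrate_mM": np.nan, "ratio": "", "replicate": r,
             "rate": control_rate} for r in range(1, replicates_control + 1)]
    for i, row in series.data.iterrows():
        rows.append({"well_id": f"D{i}", "wavelength_nm": np.nan,
                     "compound": series.agent, "dose_mM": row["dose_mM"],
                     "compound2": "", "dose2_mM": np.nan, "substrate_mM": np.nan,
                     "ratio": "", "replicate": int(row["replicate"]),
                     "rate": control_rate * (1.0 - row["fa"])})
    return pd.DataFrame(rows)


def mixture_to_rates(mix: MixtureSeries, control_rate: float = 1.0,
                     replicates_control: int = 3) -> pd.DataFrame:
    rows = [{"well_id": f"C{r}", "wavelength_nm": np.nan, "compound": "",
             "dose_mM": 0.0, "compound2": "", "dose2_mM": 0.0,
             "substrate_mM": np.nan, "ratio": "", "replicate": r,
             "rate": control_rate} for r in range(1, replicates_control + 1)]
    p, q = mix.ratio
    for i, row in mix.data.iterrows():
        d1 = mix.fraction1 * row["dose_total_mM"]
        d2 = (1.0 - mix.fraction1) * row["dose_total_mM"]
        rows.append({"well_id": f"M{i}", "wavelength_nm": np.nan,
                     "compound": mix.agent1, "dose_mM": d1,
                     "compound2": mix.agent2, "dose2_mM": d2,
                     "substrate_mM": np.nan, "ratio": f"{p}:{q}",
                     "replicate": int(row["replicate"]),
                     "rate": control_rate * (1.0 - row["fa"])})
    return pd.DataFrame(rows)


def write_truth_sidecar(truth, path) -> None:
    """Echo ground-truth parameters to a JSON sidecar for recovery tests."""
    payload = {"type": type(truth).__name__, **asdict(truth)}
    if "ratios" in payload:
        payload["ratios"] = [list(r) for r in payload["ratios"]]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_truth_sidecar(path):
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    kind = payload.pop("type")
    if kind == "KineticTruth":
        return KineticTruth(**payload)
    if kind == "MixtureTruth":
        payload["ratios"] = tuple(tuple(r) for r in payload["ratios"])
        return MixtureTruth(**payload)
    raise InputError(f"unknown truth type {kind!r}")
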