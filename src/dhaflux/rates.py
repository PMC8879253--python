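"""Growth/uptake estimation from batch curves and carbon-accounting metrics.

Covers the two unit systems used throughout the analysis:

* volumetric kinetic fluxes, mmol.min-1.L-1 (per litre of culture-equivalent
  cell volume), and
* biomass-specific stoichiometric fluxes, mmol.gDW-1.h-1.

The conversion factor between them follows from assuming dry weight is 33% of
wet weight and a cell density of 1 g/mL: 0.33 * 1000 g/L / 60 min/h = 5.5, so
``v[mmol/min/L] = 5.5 * q[mmol/gDW/h]``.

Carbon accounting works in C1 moles (moles of single carbon atoms): a hexose
taken up at q mmol/gDW/h supplies 6q mmolC1/gDW/h.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .netcore import SUBSTRATE_MOLAR_MASS, carbon_count

__all__ = [
    "GrowthCurve",
    "RateEstimate",
    "CarbonReport",
    "VOL_PER_GDW_FACTOR",
    "fit_specific_growth_rate",
    "fit_uptake_rate",
    "c1_uptake",
    "fraction_carbon_to_acetylcoa",
    "carbon_per_gdw_biomass",
    "excess_carbon_pct",
    "convert_rate_units",
    "read_growth_curve",
    "write_growth_curve",
    "carbon_report",
]

#: (gDW.min)/(L.h) — multiply a mmol/gDW/h rate by this to get mmol/min/L
VOL_PER_GDW_FACTOR = 0.33 * 1000.0 / 60.0  # = 5.5


@dataclass
class GrowthCurve:
    """Batch cultivation time series: biomass (g/L) and substrate(s) (g/L)."""

    time: np.ndarray                       # h, strictly increasing
    biomass: np.ndarray                    # g/L
    substrate: dict[str, np.ndarray] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.biomass = np.asarray(self.biomass, dtype=float)
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.biomass < 0):
            raise ValueError("biomass must be >= 0")
        for name, s in self.substrate.items():
            s = np.asarray(s, dtype=float)
            if np.any(s < 0):
                raise ValueError(f"substrate {name} has negative values")
            if len(s) != len(self.time):
                raise ValueError(f"substrate {name} length mismatch")
            self.substrate[name] = s


@dataclass
class RateEstimate:
    mu: float                  # h-1
    q_s: float | None          # mmol/gDW/h (None if only growth was fitted)
    window: tuple[float, float]
    r_squared: float


def _window_mask(time: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    t0, t1 = window
    if t0 < time[0] - 1e-12 or t1 > time[-1] + 1e-12:
        raise ValueError("window outside the curve")
    return (time >= t0 - 1e-12) & (time <= t1 + 1e-12)


def _lnlinear_fit(t: np.ndarray, x: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line through ln(x) vs t; returns (slope, intercept, R^2)."""
    y = np.log(x)
    slope, intercept = np.polyfit(t, y, 1)
    yhat = slope * t + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(slope), float(intercept), r2


def auto_growth_window(time: np.ndarray, biomass: np.ndarray,
                       min_points: int = 4, r2_min: float = 0.98
                       ) -> tuple[float, float]:
    """Longest contiguous span with ln-linear R^2 >= ``r2_min`` (ties: best R^2).

    ``r2_min`` is a floor: on cleaner data the threshold tightens towards the
    best span R^2, so a long window cannot buy its way across a growth-phase
    transition (e.g. substrate exhaustion) on the back of a loose floor.
    Falls back to the maximum-R^2 span of ``min_points`` when nothing reaches
    the threshold.
    """
    n = len(time)
    spans: list[tuple[int, float, int, int]] = []  # (length, r2, i, j)
    for i in range(n):
        for j in range(i + min_points - 1, n):
            if np.any(biomass[i:j + 1] <= 0):
                break
            _, _, r2 = _lnlinear_fit(time[i:j + 1], biomass[i:j + 1])
            spans.append((j - i + 1, r2, i, j))
    best: tuple[int, float, int, int] | None = None
    if spans:
        # judge "cleanliness" on long spans only; short spans fit well by luck
        long_len = max(min_points, n // 3)
        long_spans = [r2 for length, r2, _, _ in spans if length >= long_len]
        r2_best = max(long_spans) if long_spans else max(
            r2 for _, r2, _, _ in spans)
        threshold = max(r2_min, 1.0 - 2.0 * (1.0 - r2_best))
        for cand in spans:
            if cand[1] >= threshold and (best is None or cand[:2] > best[:2]):
                best = cand
    if best is None:
        scored = []
        for i in range(n - min_points + 1):
            j = i + min_points - 1
            if np.any(biomass[i:j + 1] <= 0):
                continue
            _, _, r2 = _lnlinear_fit(time[i:j + 1], biomass[i:j + 1])
            scored.append((r2, i, j))
        if not scored:
            raise ValueError("no usable window with positive biomass")
        _, i, j = max(scored)
        return float(time[i]), float(time[j])
    return float(time[best[2]]), float(time[best[3]])


def fit_specific_growth_rate(curve: GrowthCurve,
                             window: tuple[float, float] | None = None
                             ) -> RateEstimate:
    """Exponential approximation of the growth curve.

    mu is the least-squares slope of ln(biomass) vs time over the window; the
    window defaults to the longest contiguous ln-linear span (R^2 >= 0.98).
    """
    if window is None:
        window = auto_growth_window(curve.time, curve.biomass)
    mask = _window_mask(curve.time, window)
    t, x = curve.time[mask], curve.biomass[mask]
    if len(t) < 3:
        raise ValueError("need at least 3 points in the window")
    if np.any(x <= 0):
        raise ValueError("non-positive biomass in the window")
    slope, _, r2 = _lnlinear_fit(t, x)
    return RateEstimate(mu=max(slope, 0.0), q_s=None,
                        window=(float(window[0]), float(window[1])),
                        r_squared=r2)


def fit_uptake_rate(curve: GrowthCurve, substrate: str,
                    molar_mass: float | None = None,
                    window: tuple[float, float] | None = None) -> RateEstimate:
    """Biomass-specific uptake rate q_s (mmol/gDW/h).

    Regresses cumulative substrate consumption (mmol/L) against the integrated
    biomass curve (gDW.h/L, trapezoidal), which is exact under exponential
    growth with constant q_s and robust to the growth phase sampled.
    """
    if substrate not in curve.substrate:
        raise KeyError(f"substrate {substrate!r} not in curve")
    if molar_mass is None:
        molar_mass = SUBSTRATE_MOLAR_MASS[substrate]
    if window is None:
        window = auto_growth_window(curve.time, curve.biomass)
    mask = _window_mask(curve.time, window)
    t, x = curve.time[mask], curve.biomass[mask]
    s = curve.substrate[substrate][mask]
    if len(s) > 1 and np.polyfit(t, s, 1)[0] > 0:
        raise ValueError(f"substrate {substrate} increases over the window")
    consumed_mmol = (s[0] - s) / molar_mass * 1000.0      # mmol/L
    growth = fit_specific_growth_rate(curve, window)
    mu = growth.mu
    if mu > 0 and growth.r_squared >= 0.999:
        # exponential phase: integral X dt = (X - X0)/mu exactly, which keeps
        # the estimator quadrature-free on ideal curves
        integ_x = (x - x[0]) / mu
    else:
        integ_x = np.concatenate(([0.0], np.cumsum(
            0.5 * (x[1:] + x[:-1]) * np.diff(t))))        # gDW.h/L
    denom = float(np.sum(integ_x ** 2))
    q_s = 0.0 if denom == 0 else float(np.sum(integ_x * consumed_mmol) / denom)
    ss_res = float(np.sum((consumed_mmol - q_s * integ_x) ** 2))
    ss_tot = float(np.sum((consumed_mmol - np.mean(consumed_mmol)) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return RateEstimate(mu=mu, q_s=max(q_s, 0.0),
                        window=(float(window[0]), float(window[1])),
                        r_squared=r2)


# ---------------------------------------------------------------------------
# carbon-accounting metrics
# ---------------------------------------------------------------------------

def c1_uptake(q_s: float, n_carbon: int) -> float:
    """Substrate uptake in C1 moles, same unit system as the input rate."""
    if q_s < 0:
        raise ValueError("q_s must be >= 0")
    return n_carbon * q_s


def fraction_carbon_to_acetylcoa(v_acl: float, u_c1: float) -> float:
    """Percent of substrate carbon that ends up in cytosolic acetyl-CoA
    (2 carbons per acetyl unit produced by ATP-citrate lyase)."""
    if u_c1 <= 0:
        raise ValueError("u_c1 must be > 0")
    return 100.0 * 2.0 * v_acl / u_c1


def carbon_per_gdw_biomass(u_c1_gdw_h: float, mu: float) -> float:
    """mmol C1 consumed per gram of biomass formed (u_C1 / mu)."""
    if mu <= 0:
        raise ValueError("mu must be > 0")
    return u_c1_gdw_h / mu


def excess_carbon_pct(y_exp: float, y_opt: float) -> float:
    """Percent extra carbon used experimentally relative to the optimum."""
    if y_opt <= 0:
        raise ValueError("y_opt must be > 0")
    return 100.0 * (y_exp / y_opt - 1.0)


def convert_rate_units(value: float, direction: str = "gdw_to_vol") -> float:
    """Convert between mmol/gDW/h and mmol/min/L (factor 5.5, exact inverse)."""
    if value < 0:
        raise ValueError("value must be >= 0")
    if direction in ("gdw_to_vol", "to_volumetric"):
        return value * VOL_PER_GDW_FACTOR
    if direction in ("vol_to_gdw", "to_specific"):
        return value / VOL_PER_GDW_FACTOR
    raise ValueError(f"unknown direction {direction!r}")


@dataclass
class CarbonReport:
    """Per-substrate carbon efficiency summary (one table row)."""

    substrate: str
    q_s_gdw_h: float          # mmol/gDW/h
    q_s_vol_min: float        # mmol/min/L
    u_c1_gdw_h: float         # mmolC1/gDW/h
    u_c1_vol_min: float       # mmolC1/min/L
    mu: float                 # h-1
    y_c1x: float              # mmolC1/gDW, experimental
    y_c1x_opt: float | None = None   # mmolC1/gDW at the FBA optimum
    excess_pct: float | None = None  # % extra carbon vs optimum
    phi_accoa: float | None = None   # % substrate carbon into acetyl-CoA

    def __post_init__(self) -> None:
        expected = carbon_count(self.substrate) * self.q_s_gdw_h
        if abs(self.u_c1_gdw_h - expected) > 1e-9 * max(1.0, expected):
            raise ValueError("u_C1 must equal n_carbon * q_s exactly")


def carbon_report(substrate: str, q_s_gdw_h: float, mu: float,
                  y_c1x_opt: float | None = None,
                  v_acl_vol_min: float | None = None) -> CarbonReport:
    """Assemble the carbon-efficiency row for one substrate.

    ``v_acl_vol_min`` is the cytosolic acetyl-CoA production flux in
    mmol/min/L (kinetic units); ``y_c1x_opt`` the model-optimal carbon demand
    per gram biomass.
    """
    n_c = carbon_count(substrate)
    u_c1_gdw = c1_uptake(q_s_gdw_h, n_c)
    report = CarbonReport(
        substrate=substrate,
        q_s_gdw_h=q_s_gdw_h,
        q_s_vol_min=convert_rate_units(q_s_gdw_h, "gdw_to_vol"),
        u_c1_gdw_h=u_c1_gdw,
        u_c1_vol_min=convert_rate_units(u_c1_gdw, "gdw_to_vol"),
        mu=mu,
        y_c1x=carbon_per_gdw_biomass(u_c1_gdw, mu),
    )
    if y_c1x_opt is not None:
        report.y_c1x_opt = y_c1x_opt
        report.excess_pct = excess_carbon_pct(report.y_c1x, y_c1x_opt)
    if v_acl_vol_min is not None:
        report.phi_accoa = fraction_carbon_to_acetylcoa(
            v_acl_vol_min, report.u_c1_vol_min
        )
    return report


# ---------------------------------------------------------------------------
# curve I/O (CSV with header time_h, biomass_gL, <substrate>_gL ...)
# ---------------------------------------------------------------------------

def write_growth_curve(curve: GrowthCurve, path) -> None:
    import pandas as pd

    data = {"time_h": curve.time, "biomass_gL": curve.biomass}
    for name, s in curve.substrate.items():
        data[f"{name}_gL"] = s
    pd.DataFrame(data).to_csv(path, index=False)


def read_growth_curve(path) -> GrowthCurve:
    import pandas as pd

    df = pd.read_csv(path)
    substrates = {
        col[:-3]: df[col].to_numpy()
        for col in df.columns if col.endswith("_gL") and col != "biomass_gL"
    }
    return GrowthCurve(df["time_h"].to_numpy(), df["biomass_gL"].to_numpy(),
                       substrates)
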