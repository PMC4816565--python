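"""Two-state unfolding thermodynamics from fluorescence intensities.

Denaturation is modelled as a two-state equilibrium N ↔ D.  With fixed
native and denatured intensity anchors F_N and F_D (single emission
wavelength), the equilibrium constant at an observed intensity F_obs is

    K = (F_obs − F_N) / (F_D − F_obs),        ΔG_D = −RT ln K,

so ΔG_D crosses zero at the transition midpoint.  Plotting ΔG_D against
denaturant concentration c and fitting a line (the linear-extrapolation
model) gives the slope −m (m-value, kJ/mol per % v/v) and the intercept
ΔG° in pure water.  The analysis is repeated per protectant (trehalose)
level; a stabiliser raises ΔG_D at matched denaturant concentrations.

Points whose F_obs falls outside the open (F_N, F_D) interval are
outside the two-state signal range; they are excluded from fits with a
warning rather than clamped (clamping fabricates infinite K).

Units: energies kJ/mol, R = 8.314 J mol⁻¹ K⁻¹, T defaults to 313 K
(assays thermostatted at 40 °C).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    InsufficientDataError,
    OutOfTransitionError,
    ValidationError,
)

__all__ = [
    "R_GAS",
    "DEFAULT_TEMPERATURE",
    "UnfoldingCurve",
    "ThermoResult",
    "ActivityRecord",
    "equilibrium_constant",
    "delta_g",
    "denaturation_fit",
    "analyze_curves",
    "relative_activity",
    "read_fluorescence_csv",
]

R_GAS = 8.314  # J mol^-1 K^-1
DEFAULT_TEMPERATURE = 313.0  # K


@dataclass
class UnfoldingCurve:
    """F_obs vs denaturant concentration at one protectant level."""

    dmf_pct: np.ndarray  # % v/v
    f_obs: np.ndarray  # fluorescence intensity, a.u.
    f_n: float  # native-state anchor
    f_d: float  # denatured-state anchor (40 % DMF, no trehalose)
    temperature: float = DEFAULT_TEMPERATURE
    trehalose_molar: float = 0.0

    def __post_init__(self) -> None:
        self.dmf_pct = np.asarray(self.dmf_pct, dtype=float)
        self.f_obs = np.asarray(self.f_obs, dtype=float)
        if self.dmf_pct.shape != self.f_obs.shape:
            raise ValidationError("dmf_pct and f_obs must have equal length")
        if self.f_n == self.f_d:
            raise ValidationError("anchors F_N and F_D must differ")
        if np.any(self.dmf_pct < 0) or self.trehalose_molar < 0:
            raise ValidationError("concentrations must be non-negative")
        if self.temperature <= 0:
            raise ValidationError("temperature must be positive (K)")


@dataclass
class ThermoResult:
    """Per-point K and ΔG_D plus the linear-extrapolation fit."""

    trehalose_molar: float
    points: pd.DataFrame  # dmf_pct, K, delta_g_kJmol
    slope: float  # kJ/mol per % v/v (= −m for a denaturant)
    intercept: float  # ΔG° in water, kJ/mol
    r_squared: float
    slope_stderr: float
    excluded: list[int] = field(default_factory=list)

    @property
    def m_value(self) -> float:
        """Denaturant m-value (positive for a destabiliser), kJ/mol/%."""
        return -self.slope


def equilibrium_constant(f_obs: float, f_n: float, f_d: float) -> float:
    """K = (F_obs − F_N)/(F_D − F_obs); anchors may be in either order."""
    if f_n == f_d:
        raise ValidationError("anchors F_N and F_D must differ")
    lo, hi = min(f_n, f_d), max(f_n, f_d)
    if not lo < f_obs < hi:
        raise OutOfTransitionError(
            f"F_obs={f_obs} outside the open anchor interval ({lo}, {hi})"
        )
    return (f_obs - f_n) / (f_d - f_obs)


def delta_g(k: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """ΔG_D = −RT ln K in kJ/mol (negative when K > 1)."""
    if k <= 0:
        raise ValidationError("K must be positive")
    if temperature <= 0:
        raise ValidationError("temperature must be positive (K)")
    return -R_GAS * temperature * np.log(k) / 1000.0


def denaturation_fit(
    concentrations: np.ndarray,
    delta_gs: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[float, float, float, float]:
    """OLS line ΔG_D = intercept + slope·c.

    Returns (slope, intercept, r_squared, slope_stderr).  Weighted fits
    (inverse-variance weights) are available via ``weights``.  A
    positive slope triggers a warning — a denaturant should destabilise.
    """
    c = np.asarray(concentrations, dtype=float)
    g = np.asarray(delta_gs, dtype=float)
    if c.size < 3:
        raise InsufficientDataError("need at least 3 points to fit")
    if np.unique(c).size < 2:
        raise InsufficientDataError("need at least 2 distinct concentrations")
    if weights is None:
        res = stats.linregress(c, g)
        slope, intercept = float(res.slope), float(res.intercept)
        r2 = float(res.rvalue**2)
        stderr = float(res.stderr)
    else:
        w = np.asarray(weights, dtype=float)
        (slope, intercept), cov = np.polyfit(c, g, 1, w=np.sqrt(w), cov=True)
        pred = intercept + slope * c
        ss_res = np.sum(w * (g - pred) ** 2)
        mean_w = np.average(g, weights=w)
        ss_tot = np.sum(w * (g - mean_w) ** 2)
        r2 = float(1 - ss_res / ss_tot) if ss_tot > 0 else 1.0
        stderr = float(np.sqrt(cov[0, 0]))
        slope, intercept = float(slope), float(intercept)
    if slope > 0:
        warnings.warn(
            "positive ΔG_D vs concentration slope: the cosolvent is acting "
            "as a stabiliser, not a denaturant"
        )
    return slope, intercept, r2, stderr


def analyze_curve(curve: UnfoldingCurve) -> ThermoResult:
    """Per-point K/ΔG_D and the linear fit for a single curve."""
    ks, gs, cs, kept_idx, excluded = [], [], [], [], []
    for i, (c, f) in enumerate(zip(curve.dmf_pct, curve.f_obs)):
        try:
            k = equilibrium_constant(f, curve.f_n, curve.f_d)
        except OutOfTransitionError:
            warnings.warn(
                f"point {i} (c={c} % v/v, F_obs={f}) outside the transition "
                "region; excluded from the fit"
            )
            excluded.append(i)
            continue
        ks.append(k)
        gs.append(delta_g(k, curve.temperature))
        cs.append(c)
        kept_idx.append(i)
    if len(cs) < 3:
        raise InsufficientDataError(
            f"only {len(cs)} usable points after exclusions; need >= 3"
        )
    slope, intercept, r2, stderr = denaturation_fit(np.array(cs), np.array(gs))
    points = pd.DataFrame({"dmf_pct": cs, "K": ks, "delta_g_kJmol": gs}, index=kept_idx)
    return ThermoResult(
        trehalose_molar=curve.trehalose_molar,
        points=points,
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        slope_stderr=stderr,
        excluded=excluded,
    )


def analyze_curves(curves: list[UnfoldingCurve]) -> tuple[list[ThermoResult], pd.DataFrame]:
    """One fit per protectant level plus a ΔG_D comparison at matched c.

    All curves must share the anchor definition (same F_N and F_D, the
    latter fixed by the fully denatured reference condition).
    """
    if not curves:
        raise ValidationError("no curves supplied")
    anchor = (curves[0].f_n, curves[0].f_d)
    for cv in curves[1:]:
        if (cv.f_n, cv.f_d) != anchor:
            raise ValidationError(
                "curves disagree on the shared (F_N, F_D) anchor definition"
            )
    results = [analyze_curve(cv) for cv in curves]
    frames = []
    for res in results:
        df = res.points[["dmf_pct", "delta_g_kJmol"]].copy()
        df["trehalose_M"] = res.trehalose_molar
        frames.append(df)
    long = pd.concat(frames, ignore_index=True)
    comparison = long.pivot_table(
        index="dmf_pct", columns="trehalose_M", values="delta_g_kJmol"
    )
    return results, comparison


def relative_activity(units: float, control_units: float) -> float:
    """Residual activity as % of the control condition."""
    if control_units <= 0:
        raise ValidationError("control activity must be positive")
    return 100.0 * units / control_units


def read_fluorescence_csv(
    path: str,
    f_n: float,
    f_d: float,
    temperature: float = DEFAULT_TEMPERATURE,
) -> list[UnfoldingCurve]:
    """Read a trehalose_M,dmf_pct,F_obs CSV into per-level curves."""
    df = pd.read_csv(path)
    required = {"trehalose_M", "dmf_pct", "F_obs"}
    if not required.issubset(df.columns):
        raise ValidationError(f"CSV must have columns {sorted(required)}")
    curves = []
    for tre, grp in df.groupby("trehalose_M", sort=True):
        grp = grp.sort_values("dmf_pct")
        curves.append(
            UnfoldingCurve(
                dmf_pct=grp["dmf_pct"].to_numpy(),
                f_obs=grp["F_obs"].to_numpy(),
                f_n=f_n,
                f_d=f_d,
                temperature=temperature,
                trehalose_molar=float(tre),
            )
        )
    return curves
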