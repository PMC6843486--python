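"""Phase-solubility analysis and Van't Hoff thermodynamics.

The Higuchi–Connors phase-solubility method titrates a poorly soluble guest
against increasing host (cyclodextrin) concentration.  For a 1:1 complex the
dissolved-guest concentration rises linearly with host concentration
(A_L-type diagram) and the apparent stability constant follows from the
slope and the intrinsic solubility S0 (the intercept):

    K_c = slope / (S0 * (1 - slope))

Fitting ln K_c against 1/T (Van't Hoff plot) yields the complexation
enthalpy (dH = -slope * R) and entropy (dS = intercept * R), from which the
experimental binding free energy at a reporting temperature T is

    dG_exp = dH - T * dS

All energies are kcal/mol; concentrations molar; temperatures Kelvin.  The
gas constant default, R = 1.985e-3 kcal/(mol K), matches the value used for
the reference tables this module reproduces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SolubilitySeries",
    "SolubilityFit",
    "ThermoResult",
    "IsothermTypeError",
    "fit_isotherm",
    "vant_hoff",
    "enhancement_ratio",
    "format_fold",
    "GAS_CONSTANT_KCAL",
]

#: kcal mol^-1 K^-1
GAS_CONSTANT_KCAL = 1.985e-3


class IsothermTypeError(ValueError):
    """The isotherm cannot be typed as A_L, so K_c via the 1:1 slope
    formula is undefined."""


@dataclass
class SolubilitySeries:
    """One phase-solubility isotherm: dissolved guest vs host concentration."""

    cd_conc: np.ndarray  # M
    guest_conc: np.ndarray  # M
    temperature: float  # K
    replicate_id: str = "exp1"

    def __post_init__(self) -> None:
        self.cd_conc = np.asarray(self.cd_conc, dtype=float)
        self.guest_conc = np.asarray(self.guest_conc, dtype=float)
        if self.cd_conc.shape != self.guest_conc.shape:
            raise ValueError("cd_conc and guest_conc must be the same length")
        if np.any(self.cd_conc < 0):
            raise ValueError("host concentrations must be >= 0")
        if len(np.unique(self.cd_conc)) < 3:
            raise ValueError("need at least 3 distinct host concentrations")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cd_conc_M": self.cd_conc,
                "guest_conc_M": self.guest_conc,
                "temperature_C": self.temperature - 273.15,
                "replicate": self.replicate_id,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "list[SolubilitySeries]":
        """Split a tidy table (cd_conc_M, guest_conc_M, temperature_C,
        replicate) into one series per (temperature, replicate)."""
        out = []
        for (temp_c, rep), sub in df.groupby(["temperature_C", "replicate"]):
            out.append(
                cls(
                    sub["cd_conc_M"].to_numpy(),
                    sub["guest_conc_M"].to_numpy(),
                    temperature=float(temp_c) + 273.15,
                    replicate_id=str(rep),
                )
            )
        return out


@dataclass
class SolubilityFit:
    slope: float
    s0: float  # M, intercept = intrinsic solubility
    kc: float  # M^-1
    r2: float
    diagram_type: str  # "A_L" or "other"
    temperature: float  # K
    stderr_slope: float = float("nan")
    stderr_intercept: float = float("nan")


@dataclass
class ThermoResult:
    dh: float  # kcal/mol
    ds: float  # kcal/(mol K)
    tds: float  # kcal/mol at report_temperature
    dg_exp: float  # kcal/mol at report_temperature
    report_temperature: float  # K
    r_constant: float
    temperatures: np.ndarray = field(default_factory=lambda: np.array([]))
    r2: float = float("nan")
    stderr_slope: float = float("nan")


def fit_isotherm(
    series: SolubilitySeries,
    *,
    r2_threshold: float = 0.95,
    max_al_slope: float = 1.0,
) -> SolubilityFit:
    """Ordinary least squares of guest concentration on host concentration,
    typed as A_L when the fit is linear (r^2 >= threshold) with slope < 1.

    Raises
    ------
    IsothermTypeError
        slope >= 1, for which the 1:1 K_c formula has no meaning.
    ValueError
        non-positive intercept (intrinsic solubility).
    """
    res = stats.linregress(series.cd_conc, series.guest_conc)
    slope, s0 = float(res.slope), float(res.intercept)
    if slope >= max_al_slope:
        raise IsothermTypeError(
            f"slope {slope:.4g} >= {max_al_slope}: not A_L-typable, "
            "K_c from the 1:1 slope formula is undefined"
        )
    if s0 <= 0:
        raise ValueError(f"intercept S0 = {s0:.4g} M must be positive")
    kc = slope / (s0 * (1.0 - slope))
    r2 = float(res.rvalue) ** 2 if np.isfinite(res.rvalue) else 1.0
    dia = "A_L" if (r2 >= r2_threshold and 0.0 <= slope < max_al_slope) else "other"
    return SolubilityFit(
        slope=slope,
        s0=s0,
        kc=kc,
        r2=r2,
        diagram_type=dia,
        temperature=series.temperature,
        stderr_slope=float(res.stderr),
        stderr_intercept=float(res.intercept_stderr),
    )


def vant_hoff(
    kc_by_temperature,
    *,
    r_constant: float = GAS_CONSTANT_KCAL,
    report_temperature: float = 303.15,
) -> ThermoResult:
    """Van't Hoff regression of ln K_c on 1/T.

    Parameters
    ----------
    kc_by_temperature : iterable of (temperature K, Kc M^-1) pairs
        At least two distinct temperatures, all Kc > 0.
    report_temperature : K
        Temperature at which T*dS and dG_exp are evaluated.
    """
    pairs = [(float(t), float(k)) for t, k in kc_by_temperature]
    temps = np.array([p[0] for p in pairs])
    kcs = np.array([p[1] for p in pairs])
    if len(np.unique(temps)) < 2:
        raise ValueError("need at least 2 distinct temperatures")
    if np.any(kcs <= 0):
        raise ValueError("all Kc must be positive")
    res = stats.linregress(1.0 / temps, np.log(kcs))
    dh = -float(res.slope) * r_constant
    ds = float(res.intercept) * r_constant
    tds = report_temperature * ds
    return ThermoResult(
        dh=dh,
        ds=ds,
        tds=tds,
        dg_exp=dh - tds,
        report_temperature=report_temperature,
        r_constant=r_constant,
        temperatures=temps,
        r2=float(res.rvalue) ** 2,
        stderr_slope=float(res.stderr),
    )


def enhancement_ratio(free_solubility: float, complex_solubility: float) -> float:
    """Fold-change in guest solubility brought by complexation."""
    if free_solubility <= 0:
        raise ValueError("free solubility must be positive")
    return complex_solubility / free_solubility


def format_fold(ratio: float) -> str:
    """Nearest-integer presentation, e.g. 27.76 -> '~28x'."""
    return f"~{round(ratio):d}x"
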