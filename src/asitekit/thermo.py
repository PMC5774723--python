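"""Duplex-formation thermodynamics: UV melting and ITC analysis.

UV melting: for a non-self-complementary duplex at equal strand
concentrations c0 the association constant and duplex fraction f are
related by Ka = 2f / ((1-f)^2 c0); with the van't Hoff form
ln Ka = -dH/(R T) + dS/R the absorbance is a two-state mixture of two
sloping linear baselines.  The melting temperature Tm is where f = 0.5,
i.e. Ka(Tm) = 4/c0.

ITC: per-injection heats of a 1:1 titration follow the exact single-site
binding model (quadratic root for the bound concentration, with
volume-displacement dilution of both species); the dilution heat is
estimated from the post-saturation injections (or floated) and subtracted
before fitting (Ka, dH, n).

Free energies interconvert through dG = -R T ln Ka = dH - T dS, reported
at T_ref = 294.15 K (21 degC).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import lmfit

__all__ = [
    "R_KCAL",
    "T_REF",
    "MeltingCurve",
    "MeltFit",
    "ItcSeries",
    "ItcFit",
    "ka_from_fraction",
    "fraction_from_ka",
    "ka_of_temperature",
    "melting_absorbance",
    "melting_temperature",
    "fit_two_state",
    "vant_hoff_fit",
    "gibbs",
    "gibbs_from_ka",
    "ka_from_gibbs",
    "itc_injection_heats",
    "fit_itc",
]

#: Ideal gas constant, kcal mol^-1 K^-1.
R_KCAL = 1.987204e-3
#: Reference temperature for reported dG / TdS (21 degC).
T_REF = 294.15
C_TO_K = 273.15


# --------------------------------------------------------------------------
# Data containers
# --------------------------------------------------------------------------

@dataclass
class MeltingCurve:
    """UV melting profile: absorbance vs temperature at strand conc. c0."""

    temperature_C: np.ndarray
    absorbance: np.ndarray
    c0: float                     # molar single-strand concentration

    def __post_init__(self) -> None:
        self.temperature_C = np.asarray(self.temperature_C, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if len(self.temperature_C) != len(self.absorbance):
            raise ValueError("temperature and absorbance lengths differ")
        if np.any(np.diff(self.temperature_C) <= 0):
            raise ValueError("temperature grid must be strictly increasing")
        if self.c0 <= 0:
            raise ValueError("c0 must be positive")


@dataclass
class MeltFit:
    """Two-state melting fit result (dH/dS and sloping baselines)."""

    dH: float                     # kcal/mol
    dS: float                     # kcal/(mol K)
    baseline_folded: tuple[float, float]     # (intercept, slope)
    baseline_unfolded: tuple[float, float]
    Tm_C: float
    dG: float                     # at T_REF, kcal/mol
    TdS: float                    # at T_REF, kcal/mol
    residual: float
    success: bool = True
    message: str = ""

    @property
    def fraction(self):
        def f(temp_C: np.ndarray) -> np.ndarray:
            ka = ka_of_temperature(np.asarray(temp_C) + C_TO_K, self.dH, self.dS)
            return fraction_from_ka(ka, self._c0)
        return f

    _c0: float = field(default=np.nan, repr=False)


@dataclass
class ItcSeries:
    """Integrated per-injection heats of a titration."""

    heats: np.ndarray             # ucal per injection
    injection_volumes: np.ndarray  # L
    cell_conc: float              # M, species in the cell
    syringe_conc: float           # M, titrant
    cell_volume: float            # L

    def __post_init__(self) -> None:
        self.heats = np.asarray(self.heats, dtype=float)
        self.injection_volumes = np.asarray(self.injection_volumes, dtype=float)
        if len(self.heats) != len(self.injection_volumes):
            raise ValueError("heats and injection volumes lengths differ")
        if min(self.cell_conc, self.syringe_conc, self.cell_volume) <= 0:
            raise ValueError("concentrations and volumes must be positive")

    @property
    def molar_ratio(self) -> np.ndarray:
        """Cumulative titrant/cell molar ratio after each injection."""
        mt, xt = _dilution_series(
            self.cell_conc, self.syringe_conc, self.injection_volumes,
            self.cell_volume,
        )
        return xt / mt


@dataclass
class ItcFit:
    """1:1 binding fit of an ITC titration."""

    ka: float                     # 1/M
    dH: float                     # kcal/mol
    n: float                      # stoichiometry
    qdil: float                   # ucal per injection
    T: float                      # K
    dG: float                     # -R T ln Ka, kcal/mol
    TdS: float                    # dH - dG, kcal/mol
    residual: float
    qdil_mode: str = "post_saturation"
    success: bool = True
    message: str = ""


# --------------------------------------------------------------------------
# Core relations
# --------------------------------------------------------------------------

def ka_from_fraction(f, c0: float):
    """Ka = 2f/((1-f)^2 c0) for a non-self-complementary duplex."""
    f = np.asarray(f, dtype=float)
    if np.any((f <= 0) | (f >= 1)):
        raise ValueError("duplex fraction must be in (0, 1)")
    if c0 <= 0:
        raise ValueError("c0 must be positive")
    out = 2.0 * f / ((1.0 - f) ** 2 * c0)
    return float(out) if out.ndim == 0 else out


def fraction_from_ka(ka, c0: float):
    """Physical root (0 < f < 1) of the duplex-fraction quadratic.

    Written in the cancellation-free form f = a / (1 + a + sqrt(1 + 2a))
    with a = Ka c0, exact for all a >= 0.
    """
    a = np.asarray(ka, dtype=float) * c0
    f = a / (1.0 + a + np.sqrt(1.0 + 2.0 * a))
    return float(f) if f.ndim == 0 else f


def ka_of_temperature(T_K, dH: float, dS: float):
    """van't Hoff Ka(T) = exp(-dH/(R T) + dS/R)."""
    T_K = np.asarray(T_K, dtype=float)
    out = np.exp(-dH / (R_KCAL * T_K) + dS / R_KCAL)
    return float(out) if out.ndim == 0 else out


def melting_absorbance(
    temperature_C, dH: float, dS: float, c0: float,
    baseline_folded: tuple[float, float],
    baseline_unfolded: tuple[float, float],
):
    """Two-state absorbance with sloping linear baselines."""
    t = np.asarray(temperature_C, dtype=float)
    f = fraction_from_ka(ka_of_temperature(t + C_TO_K, dH, dS), c0)
    bf = baseline_folded[0] + baseline_folded[1] * t
    bu = baseline_unfolded[0] + baseline_unfolded[1] * t
    return f * bf + (1.0 - f) * bu


def melting_temperature(dH: float, dS: float, c0: float) -> float:
    """Tm (degC) where f = 0.5, i.e. Ka(Tm) = 4/c0 (closed form)."""
    denom = dS - R_KCAL * np.log(4.0 / c0)
    if denom == 0:
        return np.nan
    return dH / denom - C_TO_K


def gibbs(dH: float, TdS: float) -> float:
    """dG = dH - TdS (both at the same temperature), kcal/mol."""
    return dH - TdS


def gibbs_from_ka(ka: float, T_K: float = T_REF) -> float:
    """dG = -R T ln Ka, kcal/mol."""
    if ka <= 0:
        raise ValueError("Ka must be positive")
    return -R_KCAL * T_K * np.log(ka)


def ka_from_gibbs(dG: float, T_K: float = T_REF) -> float:
    return float(np.exp(-dG / (R_KCAL * T_K)))


# --------------------------------------------------------------------------
# Melting fit
# --------------------------------------------------------------------------

def fit_two_state(curve: MeltingCurve) -> MeltFit:
    """Nonlinear least-squares two-state fit with sloping baselines.

    Free parameters: dH, dS and the four baseline coefficients.  Initial
    guesses: baselines from the first/last 15% of points, Tm from the
    extremum of dA/dT, dS from the Tm relation Ka(Tm) = 4/c0.  A fit whose
    transition midpoint falls outside the measured range (the duplex
    fraction never crosses 0.5) is flagged as failed.
    """
    t = curve.temperature_C
    a = curve.absorbance
    npts = max(3, int(0.15 * len(t)))
    lo = np.polyfit(t[:npts], a[:npts], 1)      # folded side (low T)
    hi = np.polyfit(t[-npts:], a[-npts:], 1)    # unfolded side
    dadt = np.gradient(a, t)
    tm0 = float(t[np.argmax(np.abs(dadt - (np.median(dadt))))])
    if tm0 <= t[1] or tm0 >= t[-2]:
        tm0 = float(np.median(t))
    dh0 = -80.0
    ds0 = dh0 / (tm0 + C_TO_K) + R_KCAL * np.log(4.0 / curve.c0)

    params = lmfit.Parameters()
    params.add("dH", value=dh0, max=-1.0)
    params.add("dS", value=ds0, max=0.0)
    params.add("bf0", value=float(lo[1]))
    params.add("bf1", value=float(lo[0]))
    params.add("bu0", value=float(hi[1]))
    params.add("bu1", value=float(hi[0]))

    def residual(p):
        model = melting_absorbance(
            t, p["dH"].value, p["dS"].value, curve.c0,
            (p["bf0"].value, p["bf1"].value),
            (p["bu0"].value, p["bu1"].value),
        )
        return model - a

    try:
        out = lmfit.minimize(residual, params, method="leastsq")
    except Exception as err:  # pragma: no cover - defensive
        return _failed_melt_fit(curve, f"fit error: {err}")
    p = out.params
    dH, dS = p["dH"].value, p["dS"].value
    tm = melting_temperature(dH, dS, curve.c0)
    fit = MeltFit(
        dH=dH,
        dS=dS,
        baseline_folded=(p["bf0"].value, p["bf1"].value),
        baseline_unfolded=(p["bu0"].value, p["bu1"].value),
        Tm_C=tm,
        dG=dH - T_REF * dS,
        TdS=T_REF * dS,
        residual=float(np.sqrt(np.mean(out.residual**2))),
        _c0=curve.c0,
    )
    # A curve that a single straight line explains (almost) as well as the
    # two-state model carries no transition signal.
    linear = np.polyfit(t, a, 1)
    rms_linear = float(np.sqrt(np.mean((np.polyval(linear, t) - a) ** 2)))
    no_signal = rms_linear <= max(5.0 * fit.residual, 1e-3 * np.ptp(a))
    if not np.isfinite(tm) or not (t[0] < tm < t[-1]) or no_signal:
        fit.success = False
        fit.message = (
            "no biphasic transition in the measured range: the fitted duplex "
            "fraction never crosses 0.5"
        )
    return fit


def _failed_melt_fit(curve: MeltingCurve, message: str) -> MeltFit:
    return MeltFit(
        dH=np.nan, dS=np.nan, baseline_folded=(np.nan, np.nan),
        baseline_unfolded=(np.nan, np.nan), Tm_C=np.nan, dG=np.nan,
        TdS=np.nan, residual=np.nan, success=False, message=message,
        _c0=curve.c0,
    )


def vant_hoff_fit(T_K: np.ndarray, ka: np.ndarray) -> tuple[float, float]:
    """OLS of ln Ka vs 1/T: slope = -dH/R, intercept = dS/R.

    Returns (dH, dS) in kcal/mol and kcal/(mol K).
    """
    T_K = np.asarray(T_K, dtype=float)
    ka = np.asarray(ka, dtype=float)
    if np.any(ka <= 0):
        raise ValueError("Ka values must be positive")
    if len(T_K) < 3:
        raise ValueError("need at least 3 points")
    slope, intercept = np.polyfit(1.0 / T_K, np.log(ka), 1)
    return -slope * R_KCAL, intercept * R_KCAL


def vant_hoff_from_curve(
    curve: MeltingCurve, fit: MeltFit, f_window: tuple[float, float] = (0.15, 0.85)
) -> tuple[float, float]:
    """van't Hoff dH/dS from the transition region of a fitted melting curve.

    The duplex fraction is reconstructed from the fitted baselines; points
    with f outside ``f_window`` (baseline-dominated tails) are excluded.
    """
    t = curve.temperature_C
    bf = fit.baseline_folded[0] + fit.baseline_folded[1] * t
    bu = fit.baseline_unfolded[0] + fit.baseline_unfolded[1] * t
    f = (curve.absorbance - bu) / (bf - bu)
    mask = (f >= f_window[0]) & (f <= f_window[1])
    if mask.sum() < 3:
        raise ValueError("too few points inside the fraction window")
    ka = ka_from_fraction(f[mask], curve.c0)
    return vant_hoff_fit(t[mask] + C_TO_K, ka)


# --------------------------------------------------------------------------
# ITC
# --------------------------------------------------------------------------

def _dilution_series(
    cell_conc: float, syringe_conc: float, volumes: np.ndarray, v0: float
) -> tuple[np.ndarray, np.ndarray]:
    """Total cell/titrant concentrations after each injection.

    Uses the standard well-mixed displacement bookkeeping: each injection
    of volume v displaces a fraction v/V0 of both species before adding
    titrant.
    """
    mt = np.empty(len(volumes))
    xt = np.empty(len(volumes))
    m, x = cell_conc, 0.0
    for i, v in enumerate(volumes):
        d = 1.0 - v / v0
        m *= d
        x = x * d + syringe_conc * v / v0
        mt[i], xt[i] = m, x
    return mt, xt


def _bound_concentration(
    ka: float, n: float, mt: np.ndarray, xt: np.ndarray
) -> np.ndarray:
    """Bound titrant concentration from the single-site quadratic."""
    s = n * mt                      # binding-site concentration
    kd = 1.0 / ka
    b = s + xt + kd
    return 0.5 * (b - np.sqrt(b * b - 4.0 * s * xt))


def itc_injection_heats(
    ka: float,
    dH: float,
    n: float,
    cell_conc: float,
    syringe_conc: float,
    injection_volumes: np.ndarray,
    cell_volume: float,
) -> np.ndarray:
    """Exact 1:1 model heats (ucal) for a titration, no dilution heat.

    Heat of injection i is dH * V0 * (B_i - B_{i-1} (1 - v_i/V0)) where B
    is the bound concentration; the displacement factor accounts for bound
    complex expelled from the active volume.
    """
    volumes = np.asarray(injection_volumes, dtype=float)
    mt, xt = _dilution_series(cell_conc, syringe_conc, volumes, cell_volume)
    bound = _bound_concentration(ka, n, mt, xt)
    prev = np.concatenate([[0.0], bound[:-1]])
    delta = bound - prev * (1.0 - volumes / cell_volume)
    return dH * cell_volume * delta * 1e9   # kcal -> ucal


def fit_itc(
    series: ItcSeries,
    T: float = T_REF,
    qdil: float | str = "post_saturation",
    n_tail: int = 3,
) -> ItcFit:
    """Fit (Ka, dH, n) of the exact 1:1 binding model to injection heats.

    ``qdil`` controls dilution-heat handling: a float fixes it; the default
    ``"post_saturation"`` averages the last ``n_tail`` injections (falling
    back to a free parameter, with a warning, when no saturation plateau is
    detected); ``"free"`` always floats it.
    """
    heats = series.heats
    if np.ptp(heats) < 1e-12:
        return ItcFit(
            ka=np.nan, dH=0.0, n=np.nan, qdil=float(np.mean(heats)), T=T,
            dG=np.nan, TdS=np.nan, residual=0.0, success=False,
            message="all heats identical: dH = 0 and Ka is indeterminate",
        )

    mode = qdil
    qdil_fixed: float | None = None
    if isinstance(qdil, (int, float)):
        qdil_fixed, mode = float(qdil), "fixed"
    elif qdil == "post_saturation":
        tail = heats[-n_tail:]
        if np.std(tail) < 0.02 * np.ptp(heats):
            qdil_fixed = float(np.mean(tail))
        else:
            warnings.warn(
                "no saturation plateau detected; fitting the dilution heat "
                "as a free parameter",
                stacklevel=2,
            )
            mode = "free"
    elif qdil != "free":
        raise ValueError(f"unknown qdil mode {qdil!r}")

    # Initial guesses: dH from the first-injection heat, n from the
    # inflection of the heat profile, Ka from the transition sharpness.
    mt, xt = _dilution_series(
        series.cell_conc, series.syringe_conc, series.injection_volumes,
        series.cell_volume,
    )
    ratio = xt / mt
    q0 = heats - (qdil_fixed if qdil_fixed is not None else np.mean(heats[-n_tail:]))
    moles_inj = series.syringe_conc * series.injection_volumes[0]
    dh0 = float(np.clip(q0[0] * 1e-9 / moles_inj, -1e3, 1e3)) or -10.0
    half = np.nonzero(np.abs(np.cumsum(q0)) >= 0.5 * np.abs(q0.sum()))[0]
    n0 = float(ratio[half[0]]) if len(half) else 1.0
    n0 = min(max(n0, 0.1), 10.0)

    params = lmfit.Parameters()
    params.add("log_ka", value=np.log(1e6), min=np.log(1.0), max=np.log(1e14))
    params.add("dH", value=dh0)
    params.add("n", value=n0, min=1e-3)
    if qdil_fixed is None:
        params.add("qdil", value=float(np.mean(heats[-n_tail:])))

    def residual(p):
        q = itc_injection_heats(
            np.exp(p["log_ka"].value), p["dH"].value, p["n"].value,
            series.cell_conc, series.syringe_conc, series.injection_volumes,
            series.cell_volume,
        )
        qd = qdil_fixed if qdil_fixed is not None else p["qdil"].value
        return q + qd - heats

    out = lmfit.minimize(residual, params, method="leastsq")
    p = out.params
    ka = float(np.exp(p["log_ka"].value))
    dh = p["dH"].value
    qd = qdil_fixed if qdil_fixed is not None else p["qdil"].value
    dg = gibbs_from_ka(ka, T)
    return ItcFit(
        ka=ka,
        dH=dh,
        n=p["n"].value,
        qdil=float(qd),
        T=T,
        dG=dg,
        TdS=dh - dg,
        residual=float(np.sqrt(np.mean(out.residual**2))),
        qdil_mode=mode,
        success=bool(out.success),
        message="" if out.success else str(out.message),
    )
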