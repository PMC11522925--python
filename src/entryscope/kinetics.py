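"""Conventional and inverse Michaelis-Menten kinetics for interfacial
enzymes.

For an insoluble polymer substrate two complementary saturation
experiments exist: the conventional mode varies the substrate load
[S0] (g/L) at fixed enzyme concentration, while the *inverse* mode varies
the enzyme concentration [E0] (uM) at fixed substrate load -- the natural
design when the reaction happens on a surface the enzyme saturates.  Both
follow the same hyperbola

    v = V_max * x / (K_m + x)

fitted by nonlinear least squares.  Secondary parameters combine the two
modes: the conventional K_m (g/L) converts to a molar attack-site K_m via
a user-supplied conversion factor, the turnover number k_cat derives from
the inverse-mode saturation plateau, and the molar catalytic efficiency is
eta = k_cat / molar K_m.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["KineticDataset", "KineticFit", "SecondaryParams", "fit_mm",
           "secondary_params", "fold_change", "round_report"]


@dataclass
class KineticDataset:
    """One saturation series.

    ``mode`` is ``"conv"`` (x = substrate load, g/L) or ``"inv"``
    (x = enzyme concentration, uM); ``fixed_value``/``fixed_unit`` record
    the held partner.
    """

    x: np.ndarray
    rate: np.ndarray            # product formation, per minute
    mode: str = "conv"
    fixed_value: float = float("nan")
    fixed_unit: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, float)
        self.rate = np.asarray(self.rate, float)
        if self.mode not in ("conv", "inv"):
            raise ValueError("mode must be 'conv' or 'inv'")
        if len(self.x) != len(self.rate):
            raise ValueError("x and rate must have equal length")
        if np.any(self.x <= 0):
            raise ValueError("x values must be strictly positive")
        if len(np.unique(self.x)) < 4:
            raise ValueError("need at least 4 distinct x values")
        if np.any(self.rate < 0):
            raise ValueError("rates must be non-negative")


@dataclass
class KineticFit:
    """Fitted saturation parameters with linearized standard errors."""

    K_m: float
    V_max: float
    K_m_stderr: float
    V_max_stderr: float
    mode: str
    n_points: int
    rss: float
    converged: bool = True


def _mm(x: np.ndarray, V: float, K: float) -> np.ndarray:
    return V * x / (K + x)


def _initial_guess(x: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """V_max = max rate; K_m = x at half-max, linearly interpolated."""
    vmax = float(v.max())
    half = vmax / 2.0
    order = np.argsort(x)
    xs, vs = x[order], v[order]
    k = float(np.interp(half, vs, xs)) if vs[0] <= half <= vs[-1] else float(np.median(xs))
    return vmax if vmax > 0 else 1.0, max(k, float(xs[0]) * 1e-3)


def fit_mm(data: KineticDataset, max_iterations: int = 10000) -> KineticFit:
    """Nonlinear least-squares Michaelis-Menten fit.

    Raises when the rates carry no saturation information (all equal) or
    the optimizer fails to converge.
    """
    x, v = data.x, data.rate
    if np.allclose(v, v[0]):
        raise ValueError("all rates equal: V_max and K_m are unidentifiable")
    v0, k0 = _initial_guess(x, v)
    try:
        popt, pcov = curve_fit(_mm, x, v, p0=(v0, k0),
                               bounds=((0.0, 0.0), (np.inf, np.inf)),
                               maxfev=max_iterations,
                               ftol=1e-12, xtol=1e-12, gtol=1e-12)
    except RuntimeError as exc:
        raise RuntimeError(f"Michaelis-Menten fit did not converge: {exc}") from exc
    perr = np.sqrt(np.diag(pcov))
    rss = float(np.sum((v - _mm(x, *popt)) ** 2))
    return KineticFit(K_m=float(popt[1]), V_max=float(popt[0]),
                      K_m_stderr=float(perr[1]), V_max_stderr=float(perr[0]),
                      mode=data.mode, n_points=len(x), rss=rss)


@dataclass
class SecondaryParams:
    """k_cat, molar K_m and molar catalytic efficiency.

    ``molar_eta = k_cat / molar_K_m`` holds exactly.  ``k_cat_source``
    records whether k_cat was computed from the inverse-mode plateau or
    supplied directly.
    """

    k_cat: float               # 1/(min uM)
    molar_K_m: float           # uM
    molar_eta: float           # 1/(min uM^2)
    conversion: float          # g/L -> uM attack sites
    k_cat_source: str = "inverse-plateau"


def secondary_params(conv: KineticFit | None, inv: KineticFit | None,
                     conversion: float | None,
                     k_cat: float | None = None,
                     substrate_load: float | None = None,
                     molar_K_m: float | None = None) -> SecondaryParams:
    """Combine conventional and inverse fits into secondary parameters.

    ``conversion`` maps the conventional K_m (g/L) to a molar attack-site
    concentration (uM); it depends on the substrate preparation and must
    be supplied.  ``molar_K_m`` may instead be given directly (e.g. when
    recomputing a published table), bypassing the conversion.  ``k_cat``
    is taken as given when supplied; otherwise it is the inverse-mode
    V_max normalized by the fixed substrate load.
    """
    if molar_K_m is not None:
        molar_km = float(molar_K_m)
        conversion = conversion if conversion is not None else 1.0
    else:
        if conversion is None or conversion <= 0:
            raise ValueError(
                "a positive g/L -> uM attack-site conversion factor is required; "
                "it depends on the substrate preparation and cannot be defaulted")
        if conv is None or not conv.converged:
            raise ValueError("conventional fit did not converge")
        molar_km = conv.K_m * conversion
    if k_cat is not None:
        source = "supplied"
    else:
        if inv is None or not inv.converged:
            raise ValueError("supply k_cat directly or a converged inverse fit")
        if substrate_load is None or substrate_load <= 0:
            raise ValueError("substrate_load (uM attack sites) required to "
                             "normalize the inverse-mode plateau into k_cat")
        k_cat = inv.V_max / substrate_load
        source = "inverse-plateau"
    eta = k_cat / molar_km if molar_km > 0 else math.inf
    if k_cat == 0:
        eta = 0.0
    return SecondaryParams(k_cat=float(k_cat), molar_K_m=float(molar_km),
                           molar_eta=float(eta), conversion=float(conversion),
                           k_cat_source=source)


def fold_change(parent_Km: float, variant_Km: float) -> float:
    """Parent/variant K_m ratio (>1 = improved affinity of the variant)."""
    if parent_Km <= 0 or variant_Km <= 0:
        raise ValueError("K_m values must be positive")
    return parent_Km / variant_Km


def round_report(value: float, decimals: int = 3) -> float:
    """Round-half-even to report-table precision."""
    q = 10 ** decimals
    return float(np.round(value * q) / q)
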