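"""Fitting of the kICS correlation surface and confinement parameter extraction.

Single free species: ln r(k², τ) is linear in k² with slope −(D·τ + ω0²/4);
regressing the per-τ slopes against τ yields D (slope) and the PSF e⁻² radius
ω0 (from the intercept ω0²/4).

Heterogeneous (confined) diffusion: each τ row of the zero-lag-normalized CF
is fit with a sum of two Gaussian decays in k²,

    r(k², τ) = A_M·exp(−k²·g_M) + A_μ·exp(−k²·g_μ),   g_M ≥ g_μ,

the fast-decaying "macro" component tracking free motion between confinement
episodes and the slow "micro" component motion within domains.  The τ
dependence of the fitted exponents and amplitudes is then characterized:
early-lag slopes of g(τ) give the diffusion coefficients D_M and D_μ, the
late-lag mean of g_μ gives the plateau (effective confined area / 4), and the
late-lag row-renormalized amplitudes give the saturations A_M, A_μ, which are
proxies for the free / confined number fractions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .correlation import KICSCorrelation

__all__ = [
    "FitError",
    "WindowError",
    "TwoComponentFit",
    "ConfinementParameters",
    "TwoSpeciesFit",
    "fit_single_species",
    "fit_two_component",
    "extract_parameters",
    "fit_two_free_species",
]

logger = logging.getLogger("ckics")

DEFAULT_K2_MAX = 200.0  # μm⁻²; with 0.1 μm pixels this spans the full CF axis
NOISY_K2_MAX = 60.0  # μm⁻²; suggested cap at SN ≈ 5, where noise corrupts high k²
DEFAULT_EARLY_LAGS = 5  # nonzero τ rows used for the D_M / D_μ slopes
DEFAULT_LATE_FRACTION = 0.25  # trailing fraction of τ rows used for saturations


class FitError(RuntimeError):
    """A regression received unusable inputs or failed on most τ rows."""


class WindowError(RuntimeError):
    """A τ window holds too few converged rows to characterize a trend."""


def _select_bins(cf: KICSCorrelation, k2_range: tuple[float, float] | None) -> np.ndarray:
    lo, hi = k2_range if k2_range is not None else (0.0, DEFAULT_K2_MAX)
    sel = (cf.k2_grid >= lo) & (cf.k2_grid <= hi)
    if cf.mask is not None:
        sel &= cf.mask
    return sel


def fit_single_species(
    cf: KICSCorrelation,
    k2_range: tuple[float, float] | None = None,
    tau_range: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Recover (D, ω0) from an unnormalized CF of one freely diffusing species.

    Per τ, a linear fit of ln r vs k² gives slope −(D·τ + ω0²/4); a second
    linear fit of the negated slopes vs τ gives D and ω0 = 2·sqrt(intercept).
    ``tau_range`` is an inclusive (min, max) in seconds (default: all lags).
    """
    if cf.normalized:
        raise ValueError(
            "single-species fitting needs the unnormalized CF (the ω0²/4 "
            "intercept cancels under zero-lag normalization)"
        )
    sel = _select_bins(cf, k2_range)
    tau_sel = np.ones(len(cf.tau_grid), dtype=bool)
    if tau_range is not None:
        tau_sel = (cf.tau_grid >= tau_range[0]) & (cf.tau_grid <= tau_range[1])
    taus = cf.tau_grid[tau_sel]
    if len(taus) < 3:
        raise ValueError("need at least 3 τ values for the slope-of-slopes fit")

    neg_slopes = np.empty(len(taus))
    for i, row in enumerate(cf.values[tau_sel]):
        y = row[sel]
        good = np.isfinite(y) & (y > 0)
        if np.sum(good) < 4:
            raise FitError(
                f"fewer than 4 usable k² bins at τ index {i}; shrink k2_range"
            )
        x = cf.k2_grid[sel][good]
        slope, _ = np.polyfit(x, np.log(y[good]), 1)
        if not np.isfinite(slope):
            raise FitError(f"non-finite ln r vs k² slope at τ index {i}")
        neg_slopes[i] = -slope

    D, intercept = np.polyfit(taus, neg_slopes, 1)
    omega0 = 2.0 * np.sqrt(max(intercept, 0.0))
    return float(D), float(omega0)


@dataclass
class TwoComponentFit:
    """Per-τ results of the two-Gaussian decomposition of the normalized CF.

    Rows where the two components could not be distinguished from a single
    Gaussian decay (AIC) are marked ``merged``: there g_M = g_μ is the
    composite exponent and the amplitude is split evenly.
    """

    tau: np.ndarray  # s, nonzero lags
    A_M: np.ndarray
    A_mu: np.ndarray
    g_M: np.ndarray  # μm²
    g_mu: np.ndarray  # μm²
    se_g_M: np.ndarray
    se_g_mu: np.ndarray
    residual: np.ndarray  # per-τ residual norm
    converged: np.ndarray  # bool
    merged: np.ndarray  # bool: single-Gaussian row
    k2_range: tuple[float, float]
    # two-Gaussian fit of the τ-averaged trailing-quarter profile; the late
    # CF is statistically stationary there, so averaging rows before fitting
    # sharpens the saturation amplitudes and the plateau
    late_fit: dict | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tau": self.tau,
                "A_M": self.A_M,
                "A_mu": self.A_mu,
                "g_M": self.g_M,
                "g_mu": self.g_mu,
                "converged": self.converged,
                "merged": self.merged,
            }
        )


def _two_gauss(k2: np.ndarray, a_mu: float, g_mu: float, a_M: float, dg: float) -> np.ndarray:
    """Sum of two Gaussian decays, parameterized so g_M = g_mu + dg >= g_mu."""
    return a_mu * np.exp(-k2 * g_mu) + a_M * np.exp(-k2 * (g_mu + dg))


def adaptive_k2_max(cf: KICSCorrelation, k2_cap: float = DEFAULT_K2_MAX) -> float:
    """Model-based upper fitting bound in k².

    The two-Gaussian model describes the CF only below the first node of the
    domain form factor; beyond it side lobes and the pixel-locked sampling
    residue appear.  A pilot fit of the late-lag (saturated) profile within
    k² ≤ 60 μm⁻² — inside the node for any domain comparable to or larger
    than the PSF — estimates the micro exponent g_μ, and the bound is placed
    at k² = 1.5/g_μ.  The constant calibrates the node location against the
    *measured* exponent: the static enrichment pattern of a partially
    permeable domain is softer than a hard disk, so its fitted Gaussian
    exponent underestimates R²/4 by roughly a factor of three while the node
    stays at 14.7/R².  Small or unresolved domains (tiny g_μ) push the bound
    to ``k2_cap``.

    The bound only applies when the pilot exponent is actually *saturated*:
    under weak confinement the slow component of a late-lag profile is still
    the decaying macro term, whose exponent keeps growing with τ.  Pilot
    fits over a mid-series window and the trailing window must agree within
    25% before the exponent is read as a plateau (a τ-linear exponent grows
    ~1.7× between them).
    """
    pilot_sel = cf.k2_grid <= NOISY_K2_MAX
    if cf.mask is not None:
        pilot_sel &= cf.mask
    n_tau = len(cf.tau_grid) - 1
    pilot = _fit_late_profile(cf, pilot_sel, n_tau, None)
    if pilot is None or pilot["g_mu"] <= 0:
        return k2_cap
    span = max(n_tau // 8, 2)
    mid_w = (n_tau // 2, n_tau // 2 + span)
    late_w = (n_tau - span, n_tau)
    pa = _fit_late_profile(cf, pilot_sel, n_tau, None, window=mid_w)
    pb = _fit_late_profile(cf, pilot_sel, n_tau, None, window=late_w)
    if pa is None or pb is None or pa["g_mu"] <= 0:
        return k2_cap
    if pb["g_mu"] > 1.25 * pa["g_mu"]:
        return k2_cap  # still growing: macro, not a plateau
    node = 1.5 / pilot["g_mu"]
    return float(min(k2_cap, max(NOISY_K2_MAX, node)))


def _single_gauss(k2: np.ndarray, a: float, g: float) -> np.ndarray:
    return a * np.exp(-k2 * g)


def fit_two_component(
    cf: KICSCorrelation, k2_range: tuple[float, float] | None = None
) -> TwoComponentFit:
    """Fit A_M·e^(−k²g_M) + A_μ·e^(−k²g_μ) independently at every τ > 0.

    The decay is parameterized as g_M = g_μ + Δ with Δ ≥ 0, so the labeling
    invariant g_M ≥ g_μ holds by construction.  Rows are fitted from the
    latest τ (where the two decays are best separated) backwards, each row
    trying a warm start from its successor plus fresh seeds from a
    single-exponential ln-linear fit, keeping the solution with the smallest
    residual.  Bounds A ∈ [0, 2], g ∈ [0, ∞).

    At early τ both exponents shrink toward zero and the two-component
    decomposition degenerates; per row, the two-Gaussian fit is accepted
    over a single Gaussian only when it lowers the AIC, and rows where the
    second component is not supported are recorded as ``merged`` (both
    exponents set to the composite decay, amplitude split evenly) instead
    of reporting an unidentifiable split.  Non-converged rows are flagged,
    not fatal, unless they exceed half of all rows.

    With ``k2_range=None`` the upper fitting bound is chosen per series by
    :func:`adaptive_k2_max`.
    """
    if not cf.normalized:
        raise ValueError("two-component fitting expects the normalized CF")
    if k2_range is None:
        k2_range = (0.0, adaptive_k2_max(cf))
    sel = _select_bins(cf, k2_range)
    x = cf.k2_grid[sel]
    if len(x) < 8:
        raise ValueError(f"need >= 8 k² bins in range, have {len(x)}")
    used_range = (float(x.min()), float(x.max()))

    n_tau = len(cf.tau_grid) - 1
    out = {
        name: np.full(n_tau, np.nan)
        for name in ("A_M", "A_mu", "g_M", "g_mu", "se_g_M", "se_g_mu", "residual")
    }
    converged = np.zeros(n_tau, dtype=bool)
    merged = np.zeros(n_tau, dtype=bool)

    bounds2 = ([0.0, 0.0, 0.0, 0.0], [2.0, np.inf, 2.0, np.inf])
    prev: list[float] | None = None
    for i in reversed(range(n_tau)):
        y = cf.values[i + 1][sel]
        good = np.isfinite(y)
        n_pts = int(np.sum(good))
        if n_pts < 8:
            prev = None
            continue
        xg, yg = x[good], y[good]
        # composite decay rate from the ln-linear envelope
        pos = yg > 1e-12
        if np.sum(pos) >= 2:
            g0 = max(-np.polyfit(xg[pos], np.log(yg[pos]), 1)[0], 1e-6)
        else:
            g0 = 1e-3

        try:
            popt1, pcov1 = optimize.curve_fit(
                _single_gauss, xg, yg, p0=[1.0, g0],
                bounds=([0.0, 0.0], [2.0, np.inf]), maxfev=5_000,
            )
            ssr1 = float(np.sum((yg - _single_gauss(xg, *popt1)) ** 2))
        except (RuntimeError, ValueError):
            popt1, pcov1, ssr1 = None, None, np.inf

        # one balanced seed and one small-fast-component seed; the latter
        # matters at late τ where the macro survives only at the lowest k²
        seeds = [
            [0.5, g0 / 2.0, 0.5, 9.0 * g0 / 2.0],
            [0.85, g0 / 2.0, 0.15, 40.0 * g0],
        ]
        if prev is not None:
            seeds.insert(0, prev)
        best = None
        for p0 in seeds:
            try:
                popt, pcov = optimize.curve_fit(
                    _two_gauss, xg, yg, p0=p0, bounds=bounds2, maxfev=5_000
                )
            except (RuntimeError, ValueError):
                continue
            ssr = float(np.sum((yg - _two_gauss(xg, *popt)) ** 2))
            if best is None or ssr < best[0]:
                best = (ssr, popt, pcov)

        if best is None and popt1 is None:
            prev = None
            continue

        split = False
        if best is not None and popt1 is not None and n_pts > 4 and best[0] > 0:
            # AIC comparison: the 2 extra parameters must pay for themselves
            daic = n_pts * np.log(best[0] / ssr1) + 4.0
            split = daic < 0.0
        elif best is not None and popt1 is None:
            split = True

        if split:
            ssr, popt, pcov = best
            amu, gmu, aM, dg = popt
            prev = list(popt)
            perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
            out["A_M"][i], out["A_mu"][i] = aM, amu
            out["g_M"][i], out["g_mu"][i] = gmu + dg, gmu
            # dg and g_mu covary; the quadrature sum is an adequate weight
            out["se_g_M"][i] = float(np.hypot(perr[1], perr[3]))
            out["se_g_mu"][i] = perr[1]
            out["residual"][i] = float(np.sqrt(ssr))
        else:
            a, g = popt1
            prev = [a / 2.0, g, a / 2.0, 0.0]
            se_g = float(np.sqrt(max(pcov1[1, 1], 0.0)))
            out["A_M"][i] = out["A_mu"][i] = a / 2.0
            out["g_M"][i] = out["g_mu"][i] = g
            out["se_g_M"][i] = out["se_g_mu"][i] = se_g
            out["residual"][i] = float(np.sqrt(ssr1))
            merged[i] = True
        converged[i] = True

    n_fail = int(np.sum(~converged))
    if n_fail:
        logger.warning("%d/%d τ rows did not converge in the two-component fit", n_fail, n_tau)
    if n_fail > n_tau / 2:
        raise FitError(f"{n_fail}/{n_tau} τ rows failed to converge")

    split_rows = np.flatnonzero(converged & ~merged)
    if len(split_rows):
        j = split_rows[-1]
        warm = [
            out["A_mu"][j], out["g_mu"][j],
            out["A_M"][j], out["g_M"][j] - out["g_mu"][j],
        ]
    else:
        warm = None
    late_fit = _fit_late_profile(cf, sel, n_tau, warm)

    return TwoComponentFit(
        tau=cf.tau_grid[1:],
        A_M=out["A_M"],
        A_mu=out["A_mu"],
        g_M=out["g_M"],
        g_mu=out["g_mu"],
        se_g_M=out["se_g_M"],
        se_g_mu=out["se_g_mu"],
        residual=out["residual"],
        converged=converged,
        merged=merged,
        k2_range=used_range,
        late_fit=late_fit,
    )


def _fit_late_profile(cf: KICSCorrelation, sel: np.ndarray, n_tau: int,
                      warm: list[float] | None,
                      window: tuple[int, int] | None = None) -> dict | None:
    """Two-Gaussian fit of the τ-averaged trailing-quarter CF profile.

    The saturated (late-τ) CF is statistically stationary, so averaging its
    rows before fitting raises the power to resolve a weak macro remnant.
    When even the averaged profile supports only a single Gaussian, the
    surviving slow decay is attributed to the micro component (the macro has
    decayed away): A_M = 0.
    """
    if window is None:
        start = n_tau - max(int(round(n_tau * DEFAULT_LATE_FRACTION)), 3)
        stop = n_tau
    else:
        start, stop = window
    if start < 0 or stop <= start:
        return None
    x_all = cf.k2_grid[sel]
    profile = np.nanmean(cf.values[start + 1 : stop + 1][:, sel], axis=0)
    good = np.isfinite(profile)
    n_pts = int(np.sum(good))
    if n_pts < 8:
        return None
    xg, yg = x_all[good], profile[good]
    pos = yg > 1e-12
    if np.sum(pos) < 2:
        return None
    g0 = max(-np.polyfit(xg[pos], np.log(yg[pos]), 1)[0], 1e-6)
    try:
        popt1, _ = optimize.curve_fit(
            _single_gauss, xg, yg, p0=[1.0, g0],
            bounds=([0.0, 0.0], [2.0, np.inf]), maxfev=5_000,
        )
        ssr1 = float(np.sum((yg - _single_gauss(xg, *popt1)) ** 2))
    except (RuntimeError, ValueError):
        return None
    seeds = [
        [0.5, g0 / 2.0, 0.5, 9.0 * g0 / 2.0],
        [0.85, g0 / 2.0, 0.15, 40.0 * g0],
        [0.9, g0, 0.1, 100.0 * g0],
    ]
    if warm is not None:
        seeds.insert(0, warm)
    best = None
    for p0 in seeds:
        try:
            popt, _ = optimize.curve_fit(
                _two_gauss, xg, yg, p0=p0,
                bounds=([0.0, 0.0, 0.0, 0.0], [2.0, np.inf, 2.0, np.inf]),
                maxfev=5_000,
            )
        except (RuntimeError, ValueError):
            continue
        ssr = float(np.sum((yg - _two_gauss(xg, *popt)) ** 2))
        if best is None or ssr < best[0]:
            best = (ssr, popt)
    split = False
    if best is not None and best[0] > 0:
        daic = n_pts * np.log(best[0] / ssr1) + 4.0
        split = daic < 0.0
    if split:
        amu, gmu, aM, dg = best[1]
        return {
            "A_M": float(aM), "A_mu": float(amu),
            "g_M": float(gmu + dg), "g_mu": float(gmu),
            "merged": False, "window": (start, stop),
        }
    a, g = popt1
    return {
        "A_M": 0.0, "A_mu": float(a), "g_M": float(g), "g_mu": float(g),
        "merged": True, "window": (start, stop),
    }


@dataclass
class ConfinementParameters:
    """The five headline confinement outputs plus windows and diagnostics.

    ``plateau_mu`` is the late-τ mean of the micro exponent g_μ (μm²); since a
    Gaussian exponent carries MSD/4 and the steady-state 2D MSD in a circular
    corral of radius R is ≈ R², the matching length convention is
    ``effective_radius`` = 2·sqrt(plateau_mu).
    """

    D_M: float  # μm²/s, large-spatial-scale (macro) diffusion
    D_mu: float  # μm²/s, small-spatial-scale (micro) diffusion
    plateau_mu: float  # μm², late-τ saturation of g_μ
    sat_A_M: float  # late-τ macro amplitude fraction
    sat_A_mu: float  # late-τ micro amplitude fraction
    effective_radius: float  # μm, 2·sqrt(plateau_mu)
    early_window: tuple[int, int]  # τ-row index range [start, stop)
    late_window: tuple[int, int]
    ci: dict = field(default_factory=dict)  # parameter -> (lo, hi), ~95%

    def to_dict(self) -> dict:
        return {
            "D_M": self.D_M,
            "D_mu": self.D_mu,
            "plateau_mu": self.plateau_mu,
            "sat_A_M": self.sat_A_M,
            "sat_A_mu": self.sat_A_mu,
            "effective_radius": self.effective_radius,
            "early_window": list(self.early_window),
            "late_window": list(self.late_window),
            "ci": {k: list(v) for k, v in self.ci.items()},
        }


def _wls_slope(x: np.ndarray, y: np.ndarray, se: np.ndarray) -> tuple[float, float]:
    """Weighted least-squares line through (x, y); returns (slope, slope SE)."""
    w = np.where(np.isfinite(se) & (se > 0), 1.0 / se**2, np.nan)
    if not np.all(np.isfinite(w)):
        w = np.ones_like(x)
    W = np.sum(w)
    xbar = np.sum(w * x) / W
    ybar = np.sum(w * y) / W
    sxx = np.sum(w * (x - xbar) ** 2)
    slope = np.sum(w * (x - xbar) * (y - ybar)) / sxx
    resid = y - ybar - slope * (x - xbar)
    dof = max(len(x) - 2, 1)
    se_slope = np.sqrt(np.sum(w * resid**2) / dof / sxx)
    return float(slope), float(se_slope)


def extract_parameters(
    fit: TwoComponentFit,
    early_window: tuple[int, int] | None = None,
    late_window: tuple[int, int] | None = None,
) -> ConfinementParameters:
    """Characterize the τ trends of a two-component fit.

    Windows are [start, stop) index ranges into the nonzero-τ rows.  Defaults:
    the first 5 rows (early) and the trailing 25% (late).  D_M and D_μ are the
    early-window weighted slopes of g_M(τ) and g_μ(τ); the plateau and
    amplitude saturations are late-window means, amplitudes renormalized per
    row by A_M + A_μ so they read as fractions.
    """
    n = len(fit.tau)
    expand_early = early_window is None
    if early_window is None:
        early_window = (0, min(DEFAULT_EARLY_LAGS, n))
    use_profile = (
        late_window is None
        and fit.late_fit is not None
    )
    if late_window is None:
        late_window = (n - max(int(round(n * DEFAULT_LATE_FRACTION)), 3), n)

    def window_rows(window: tuple[int, int], name: str, extra=None) -> np.ndarray:
        start, stop = window
        if not (0 <= start < stop <= n):
            raise WindowError(f"{name} window {window} outside τ rows [0, {n})")
        keep = fit.converged[start:stop].copy()
        if extra is not None:
            keep &= extra[start:stop]
        rows = np.arange(start, stop)[keep]
        if len(rows) < 3:
            raise WindowError(
                f"{name} window {window} has {len(rows)} usable rows (< 3)"
            )
        return rows

    # a split row with a vanishing amplitude carries no information about
    # that component's exponent; merged rows carry the composite decay
    informative_M = fit.merged | (fit.A_M >= 0.01)
    informative_mu = fit.merged | (fit.A_mu >= 0.01)

    def early_rows(extra) -> np.ndarray:
        window = early_window
        while True:
            try:
                return window_rows(window, "early", extra)
            except WindowError:
                # the default early window may be starved of usable rows in
                # a sparse fit; stretch it rather than fail the whole run
                if not expand_early or window[1] >= n:
                    raise
                window = (window[0], min(window[1] + 5, n))

    early_M = early_rows(informative_M)
    early_mu = early_rows(informative_mu)
    late = window_rows(late_window, "late", informative_mu)

    D_M, se_DM = _wls_slope(fit.tau[early_M], fit.g_M[early_M], fit.se_g_M[early_M])
    D_mu, se_Dmu = _wls_slope(fit.tau[early_mu], fit.g_mu[early_mu], fit.se_g_mu[early_mu])

    plateau_rows = fit.g_mu[late]
    se_plateau = float(np.std(plateau_rows, ddof=1) / np.sqrt(len(plateau_rows)))

    if use_profile:
        # the τ-averaged late profile is the sharper estimator of the
        # saturated quantities (late rows are statistically stationary)
        lf = fit.late_fit
        plateau = lf["g_mu"]
        total = lf["A_M"] + lf["A_mu"]
        sat_M = lf["A_M"] / total
        sat_mu = lf["A_mu"] / total
        frac_M_rows = fit.A_M[late] / (fit.A_M[late] + fit.A_mu[late])
        se_satM = se_satmu = float(
            np.std(frac_M_rows, ddof=1) / np.sqrt(len(frac_M_rows))
        )
    else:
        plateau = float(np.mean(plateau_rows))
        # amplitude fractions are meaningful only where the split is
        # resolved; fall back to all converged rows if no late row splits
        split_late = np.arange(*late_window)[
            (fit.converged & ~fit.merged)[slice(*late_window)]
        ]
        amp_rows = split_late if len(split_late) >= 3 else late
        total = fit.A_M[amp_rows] + fit.A_mu[amp_rows]
        frac_M = fit.A_M[amp_rows] / total
        frac_mu = fit.A_mu[amp_rows] / total
        sat_M = float(np.mean(frac_M))
        sat_mu = float(np.mean(frac_mu))
        se_satM = float(np.std(frac_M, ddof=1) / np.sqrt(max(len(frac_M), 2)))
        se_satmu = float(np.std(frac_mu, ddof=1) / np.sqrt(max(len(frac_mu), 2)))

    z = 1.96
    ci = {
        "D_M": (D_M - z * se_DM, D_M + z * se_DM),
        "D_mu": (D_mu - z * se_Dmu, D_mu + z * se_Dmu),
        "plateau_mu": (plateau - z * se_plateau, plateau + z * se_plateau),
        "sat_A_M": (sat_M - z * se_satM, sat_M + z * se_satM),
        "sat_A_mu": (sat_mu - z * se_satmu, sat_mu + z * se_satmu),
    }
    return ConfinementParameters(
        D_M=D_M,
        D_mu=D_mu,
        plateau_mu=plateau,
        sat_A_M=sat_M,
        sat_A_mu=sat_mu,
        effective_radius=2.0 * np.sqrt(max(plateau, 0.0)),
        early_window=early_window,
        late_window=late_window,
        ci=ci,
    )


@dataclass(frozen=True)
class TwoSpeciesFit:
    """Global two-free-species fit: exponents constrained to D·τ."""

    D1: float  # μm²/s, faster species
    D2: float  # μm²/s, slower species
    N1_frac: float  # number fraction of species 1
    degenerate: bool  # D1 ≈ D2: the data support only one species


def fit_two_free_species(
    cf: KICSCorrelation, k2_range: tuple[float, float] | None = None
) -> TwoSpeciesFit:
    """Fit N1·e^(−k²D1τ) + (1−N1)·e^(−k²D2τ) globally across all τ > 0.

    Validation mode for a mixture of two non-interconverting free species,
    where both exponents must stay linear in τ.  D1 ≥ D2 by labeling; a
    relative gap below 5% is reported as degenerate (single species).
    """
    if not cf.normalized:
        raise ValueError("two-free-species fitting expects the normalized CF")
    sel = _select_bins(cf, k2_range)
    k2 = cf.k2_grid[sel]
    if len(k2) < 8:
        raise ValueError(f"need >= 8 k² bins in range, have {len(k2)}")
    taus = cf.tau_grid[1:]
    K2, TAU = np.meshgrid(k2, taus)
    Y = cf.values[1:][:, sel]
    good = np.isfinite(Y.ravel())
    x = np.stack([K2.ravel()[good], TAU.ravel()[good]])
    y = Y.ravel()[good]

    # seed from the global single-species decay rate
    pos = y > 1e-12
    kt = x[0] * x[1]
    d_hat = max(-np.polyfit(kt[pos], np.log(y[pos]), 1)[0], 1e-6)

    def model(x, d1, d2, n1):
        k2tau = x[0] * x[1]
        return n1 * np.exp(-k2tau * d1) + (1.0 - n1) * np.exp(-k2tau * d2)

    try:
        popt, _ = optimize.curve_fit(
            model,
            x,
            y,
            p0=[2.0 * d_hat, 0.5 * d_hat, 0.5],
            bounds=([0.0, 0.0, 0.0], [np.inf, np.inf, 1.0]),
            maxfev=20_000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"two-free-species global fit failed: {exc}") from exc
    d1, d2, n1 = popt
    if d1 < d2:
        d1, d2, n1 = d2, d1, 1.0 - n1
    degenerate = (d1 - d2) <= 0.05 * max(d1, 1e-300)
    if degenerate:
        logger.warning(
            "two-free-species fit is degenerate (D1 ≈ D2 ≈ %.3g μm²/s)", d1
        )
    return TwoSpeciesFit(float(d1), float(d2), float(n1), bool(degenerate))
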