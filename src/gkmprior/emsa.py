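"""EMSA binding-curve quantification: background correction, fraction bound,
one-site specific-binding regression, and ref-vs-alt allele comparison.

Band intensities from a gel shift experiment are corrected by subtracting a
blank-region background (clamping at zero: blank-region noise routinely
exceeds faint bands), converted to a bound fraction

    Y = bound / (bound + unbound),

and fitted against protein concentration X (nM) with the one-site specific
binding model

    Y = Bmax * X / (Kd + X)

by unweighted nonlinear least squares. Replicates are pooled into one fit
by default, preserving the error structure; an averaged mode mirrors
plotting mean curves. Standard errors come from the local curvature
(Jacobian-based covariance) at the optimum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


@dataclass
class LaneQuantification:
    lane: str
    concentration: float  # nM
    bound_intensity: float  # background-corrected, >= 0
    unbound_intensity: float
    background_intensity: float

    def __post_init__(self):
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if self.bound_intensity < 0 or self.unbound_intensity < 0:
            raise ValueError("corrected intensities must be >= 0")


@dataclass
class BindingPoint:
    concentration: float  # X, nM
    fraction_bound: float  # Y in [0, 1]
    replicate: str = "r1"

    def __post_init__(self):
        if not (0.0 <= self.fraction_bound <= 1.0):
            raise ValueError("fraction bound must lie in [0, 1]")


@dataclass
class BindingFit:
    bmax: float
    kd: float  # nM
    bmax_se: float
    kd_se: float
    rss: float
    converged: bool
    n_points: int = 0

    def __post_init__(self):
        if self.converged and (self.kd <= 0 or self.bmax <= 0):
            raise ValueError("a converged fit requires kd > 0 and bmax > 0")

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        return self.bmax * x / (self.kd + x)


def correct_background(bound_raw: float, unbound_raw: float, background: float):
    """Subtract blank-region background from both band intensities.

    Corrected intensities floor at zero; returns (bound, unbound, clamped)
    where ``clamped`` flags whether any value hit the floor.
    """
    if bound_raw < 0 or unbound_raw < 0:
        raise ValueError("raw intensities must be non-negative")
    bound = bound_raw - background
    unbound = unbound_raw - background
    clamped = bound < 0 or unbound < 0
    return max(bound, 0.0), max(unbound, 0.0), clamped


def fraction_bound(bound: float, unbound: float) -> float:
    """Fraction of DNA bound: bound / (bound + unbound)."""
    total = bound + unbound
    if total <= 0:
        raise ValueError("bound + unbound must be positive")
    return bound / total


def lanes_to_points(lanes: pd.DataFrame, average_replicates: bool = False):
    """Convert a lane table to binding points.

    Expects columns (lane, concentration_nM, bound, unbound, background)
    with optional ``replicate``. Lanes whose corrected intensities are both
    zero are undefined and reported rather than fitted.
    """
    points, undefined = [], []
    for row in lanes.itertuples(index=False):
        b, u, _ = correct_background(float(row.bound), float(row.unbound), float(row.background))
        if b + u <= 0:
            undefined.append((str(row.lane), "bound and unbound both zero after correction"))
            continue
        points.append(
            BindingPoint(
                concentration=float(row.concentration_nM),
                fraction_bound=min(fraction_bound(b, u), 1.0),
                replicate=str(getattr(row, "replicate", "r1")),
            )
        )
    if average_replicates:
        df = pd.DataFrame(
            [(p.concentration, p.fraction_bound) for p in points], columns=["x", "y"]
        )
        mean = df.groupby("x", as_index=False)["y"].mean()
        points = [BindingPoint(x, y, "mean") for x, y in zip(mean["x"], mean["y"])]
    return points, undefined


def _one_site(x, bmax, kd):
    return bmax * x / (kd + x)


def fit_one_site(points: list[BindingPoint], constrain_bmax: bool = False) -> BindingFit:
    """Least-squares fit of the one-site specific-binding model.

    Initialization: Bmax0 = max(Y); Kd0 = X of the point whose Y is nearest
    Bmax0/2. Requires >= 3 distinct concentrations; all-equal Y values make
    Kd unidentifiable and raise. ``constrain_bmax`` caps Bmax at 1.
    """
    x = np.array([p.concentration for p in points], dtype=float)
    y = np.array([p.fraction_bound for p in points], dtype=float)
    if np.any(x <= 0):
        raise ValueError("concentrations must be positive for fitting")
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct concentrations")
    if np.ptp(y) < 1e-12:
        raise ValueError("all fraction-bound values equal: Kd is unidentifiable")
    bmax0 = float(y.max())
    kd0 = float(x[np.argmin(np.abs(y - bmax0 / 2))])
    bounds = ([0.0, 0.0], [1.0, np.inf]) if constrain_bmax else ([0.0, 0.0], [np.inf, np.inf])
    try:
        popt, pcov = curve_fit(
            _one_site, x, y, p0=[bmax0, max(kd0, 1e-6)], bounds=bounds,
            xtol=1e-12, ftol=1e-12, gtol=1e-12, maxfev=20000,
        )
        converged = bool(np.all(np.isfinite(popt)))
    except RuntimeError:
        return BindingFit(np.nan, np.nan, np.nan, np.nan, np.nan, False, len(points))
    resid = y - _one_site(x, *popt)
    ses = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else [np.nan, np.nan]
    return BindingFit(
        bmax=float(popt[0]), kd=float(popt[1]),
        bmax_se=float(ses[0]), kd_se=float(ses[1]),
        rss=float((resid**2).sum()), converged=converged, n_points=len(points),
    )


@dataclass
class AlleleComparison:
    delta_kd: float  # kd_alt - kd_ref
    kd_ratio: float  # kd_alt / kd_ref
    direction: str  # increased / decreased / unchanged binding of the alt allele


def compare_alleles(fit_ref: BindingFit, fit_alt: BindingFit) -> AlleleComparison:
    """Call the direction of the allele effect on binding.

    A lower Kd means higher affinity: the call is "increased" when
    Kd_alt < Kd_ref beyond the combined standard error, "decreased" for the
    reverse, else "unchanged". Unconverged fits raise.
    """
    if not (fit_ref.converged and fit_alt.converged):
        raise ValueError("both fits must have converged")
    dkd = fit_alt.kd - fit_ref.kd
    se = np.hypot(
        fit_ref.kd_se if np.isfinite(fit_ref.kd_se) else 0.0,
        fit_alt.kd_se if np.isfinite(fit_alt.kd_se) else 0.0,
    )
    if dkd < -se:
        direction = "increased"
    elif dkd > se:
        direction = "decreased"
    else:
        direction = "unchanged"
    return AlleleComparison(delta_kd=dkd, kd_ratio=fit_alt.kd / fit_ref.kd, direction=direction)


def fit_to_json(fit: BindingFit, path: str | Path) -> None:
    Path(path).write_text(json.dumps({
        "bmax": fit.bmax, "kd_nM": fit.kd, "bmax_se": fit.bmax_se,
        "kd_se": fit.kd_se, "rss": fit.rss, "converged": fit.converged,
        "n_points": fit.n_points,
    }, indent=2))


def plot_binding_curve(points, fit: BindingFit, path: str | Path, title: str = "") -> None:
    """Optional diagnostic plot (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.array([p.concentration for p in points])
    y = np.array([p.fraction_bound for p in points])
    grid = np.linspace(0, x.max() * 1.05, 200)
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.plot(x, y, "o", label="data")
    ax.plot(grid, fit.predict(grid), "-", label=f"fit Kd={fit.kd:.0f} nM")
    ax.set_xlabel("[TF] (nM)")
    ax.set_ylabel("fraction bound")
    ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
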