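"""Recovery of the effective attenuation coefficient from reflectance scans.

The measured profile is linearised with ``ln(rho**2 * Gamma)`` and fitted
by ordinary least squares; the slope estimates ``-mu_eff``.  Given one
known coefficient the other follows from ``mu_eff**2 = 3 mu_a mu_s'``.
Detection failure (all samples absorbed below the noise floor) is a
reported state, not a pipeline-stopping exception: concentration-ladder
comparisons continue with the phantoms that could be measured.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .optical import (
    InsufficientDataError,
    ReflectanceProfile,
    log_rho2_transform,
)

__all__ = [
    "DrFitResult",
    "DiffusionSlopeRegressor",
    "fit_dr_slope",
    "invert_absorption",
    "compare_slopes",
    "plot_slope_comparison",
]


@dataclass(frozen=True)
class DrFitResult:
    """Outcome of one attenuation-slope fit.

    ``mu_eff_hat`` is exactly ``-slope`` (per mm); ``r_squared`` is the OLS
    coefficient of determination on the transformed points.
    """

    slope: float
    intercept: float
    mu_eff_hat: float
    r_squared: float
    n_used: int
    n_excluded: int

    def __post_init__(self) -> None:
        if self.n_used < 2:
            raise ValueError("a slope fit needs n_used >= 2")


class DiffusionSlopeRegressor(BaseEstimator):
    """OLS estimator of the attenuation slope of ``ln(rho**2 * Gamma)``.

    Parameters
    ----------
    rho_window : tuple of (float, float), optional
        Restrict the fit to separations ``rho_min <= rho <= rho_max`` (mm).
        Default is the full profile.

    Attributes
    ----------
    slope_ : float
        Fitted slope (per mm, negative for an absorbing medium).
    intercept_ : float
        Fitted intercept; estimates ln(c1).
    mu_eff_ : float
        ``-slope_``, the effective attenuation estimate.
    r_squared_ : float
    n_used_ : int
    n_excluded_ : int
        Samples dropped for being non-positive or below the noise floor,
        plus any outside the window.
    result_ : DrFitResult
    """

    def __init__(self, rho_window: tuple[float, float] | None = None):
        self.rho_window = rho_window

    def fit(self, profile: ReflectanceProfile) -> "DiffusionSlopeRegressor":
        rho, y, n_excluded = log_rho2_transform(profile)
        if self.rho_window is not None:
            lo, hi = self.rho_window
            keep = (rho >= lo) & (rho <= hi)
            n_excluded += int(np.count_nonzero(~keep))
            rho, y = rho[keep], y[keep]
            if rho.size < 2:
                raise InsufficientDataError(
                    "fewer than 2 samples left inside the rho window"
                )
        if np.ptp(rho) == 0:
            raise ValueError("degenerate profile: all separations identical")

        # OLS on the linearised points; slope in per-mm.
        slope, intercept = np.polyfit(rho, y, 1)
        resid = y - (slope * rho + intercept)
        ss_res = float(resid @ resid)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot

        self.slope_ = float(slope)
        self.intercept_ = float(intercept)
        self.mu_eff_ = -float(slope)
        self.r_squared_ = float(r2)
        self.n_used_ = int(rho.size)
        self.n_excluded_ = int(n_excluded)
        self.result_ = DrFitResult(
            slope=self.slope_,
            intercept=self.intercept_,
            mu_eff_hat=self.mu_eff_,
            r_squared=self.r_squared_,
            n_used=self.n_used_,
            n_excluded=self.n_excluded_,
        )
        return self

    def predict(self, rho: Sequence[float] | np.ndarray) -> np.ndarray:
        """Predicted ln(rho**2 * Gamma) at the given separations."""
        if not hasattr(self, "slope_"):
            raise RuntimeError("regressor is not fitted")
        return self.slope_ * np.asarray(rho, dtype=float) + self.intercept_


def fit_dr_slope(
    profile: ReflectanceProfile,
    rho_window: tuple[float, float] | None = None,
) -> DrFitResult:
    """Fit the attenuation line to one profile; returns a :class:`DrFitResult`."""
    return DiffusionSlopeRegressor(rho_window=rho_window).fit(profile).result_


def invert_absorption(mu_eff_hat: float, mu_s_prime_known: float) -> float:
    """Recover mu_a from a mu_eff estimate and a known mu_s'.

    Inverts mu_eff = sqrt(3 mu_a mu_s'):  mu_a = mu_eff**2 / (3 mu_s').
    """
    if mu_s_prime_known <= 0:
        raise ValueError(f"mu_s_prime must be > 0, got {mu_s_prime_known}")
    if mu_eff_hat < 0:
        raise ValueError(f"mu_eff_hat must be >= 0, got {mu_eff_hat}")
    return float(mu_eff_hat**2 / (3.0 * mu_s_prime_known))


def compare_slopes(
    results: Iterable[tuple[str, DrFitResult | None]],
    sort_by: str | None = None,
    ascending: bool = True,
) -> pd.DataFrame:
    """Tabulate slope fits across phantoms for a concentration-ladder comparison.

    ``None`` in place of a fit result marks a phantom whose profile fell
    entirely below the detection floor; the row is kept with
    ``detected=False`` so the comparison mirrors measurement campaigns in
    which some high-absorption samples simply return nothing.
    """
    rows = []
    for label, res in results:
        if res is None:
            rows.append(
                {
                    "label": label,
                    "slope": np.nan,
                    "mu_eff_hat": np.nan,
                    "r_squared": np.nan,
                    "n_used": 0,
                    "n_excluded": np.nan,
                    "detected": False,
                }
            )
        else:
            rows.append(
                {
                    "label": label,
                    "slope": res.slope,
                    "mu_eff_hat": res.mu_eff_hat,
                    "r_squared": res.r_squared,
                    "n_used": res.n_used,
                    "n_excluded": res.n_excluded,
                    "detected": True,
                }
            )
    if not rows:
        raise ValueError("compare_slopes requires at least one entry")
    table = pd.DataFrame(rows)
    if sort_by is not None:
        table = table.sort_values(sort_by, ascending=ascending, kind="stable")
        table = table.reset_index(drop=True)
    return table


def plot_slope_comparison(table: pd.DataFrame, path: str | Path) -> None:
    """Render the slope table as a bar chart (undetected phantoms hatched empty)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, 0.9 * len(table)), 4))
    x = np.arange(len(table))
    heights = table["slope"].fillna(0.0).to_numpy()
    colors = ["C0" if d else "0.85" for d in table["detected"]]
    ax.bar(x, heights, color=colors, edgecolor="k")
    for xi, det in zip(x, table["detected"]):
        if not det:
            ax.text(xi, 0, "n.d.", ha="center", va="bottom", fontsize=8)
    ax.set_xticks(x)
    ax.set_xticklabels(table["label"], rotation=45, ha="right", fontsize=8)
    ax.set_ylabel(r"slope of $\ln(\rho^2\Gamma)$ [mm$^{-1}$]")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
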