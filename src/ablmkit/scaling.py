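"""FixedData-profile scaling analysis.

At a fixed training-data scale, evaluation loss as a function of model
size is well described by a quadratic in x = log10(parameter count); the
parabola's minimum is the data-optimal model size for that data scale.
Fitting a power law through the (optimal model size, data size) minima of
several data scales yields a data-optimal scaling law

    data_size = alpha * model_size ** beta

which can be evaluated in either direction (how much data a given model
needs; how large a model a given corpus supports).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "LossGridPoint",
    "FixedDataProfile",
    "PowerLaw",
    "exclude_outliers",
    "fit_fixeddata_profile",
    "fit_power_law",
    "predict_optimal_data",
    "predict_optimal_model",
]


class InsufficientDataError(ValueError):
    pass


class NonConvexProfileError(ValueError):
    pass


@dataclass
class LossGridPoint:
    param_count: int
    data_scale_id: str
    data_size: int
    mean_loss: float
    included_in_fit: bool = True

    def __post_init__(self):
        if self.param_count <= 0:
            raise ValueError("param_count must be positive")
        if self.mean_loss <= 0:
            raise ValueError("mean_loss must be positive")


@dataclass
class FixedDataProfile:
    data_scale_id: str
    a: float
    b: float
    c: float
    r_squared: float
    optimal_param_count: float
    n_points: int = 0


@dataclass
class PowerLaw:
    alpha: float
    beta: float
    r_squared: float = 1.0

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")


def exclude_outliers(points, loss_factor: float = 1.5):
    """Mark which grid points of one data scale enter the quadratic fit.

    Points whose loss exceeds the minimum loss by more than ``loss_factor``
    times are dropped, but the minimum-loss point and its nearest
    neighbours in log-size are always retained so at least 3 points
    survive. Returns the points with ``included_in_fit`` set.
    """
    points = list(points)
    if len(points) < 3:
        raise InsufficientDataError(f"need >= 3 points, got {len(points)}")
    order = sorted(range(len(points)), key=lambda i: np.log10(points[i].param_count))
    losses = [points[i].mean_loss for i in order]
    min_pos = int(np.argmin(losses))
    min_loss = losses[min_pos]

    keep = {min_pos}
    # walk outward from the minimum, nearest log-size neighbours first
    left, right = min_pos - 1, min_pos + 1
    candidates = []
    while left >= 0 or right < len(order):
        if left >= 0:
            candidates.append(left)
            left -= 1
        if right < len(order):
            candidates.append(right)
            right += 1
    for pos in candidates:
        if len(keep) < 3 or losses[pos] <= loss_factor * min_loss:
            keep.add(pos)
    for rank, idx in enumerate(order):
        points[idx].included_in_fit = rank in keep
    return points


def _quadratic_ols(x, y):
    X = np.column_stack([x * x, x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return coef, r2


def fit_fixeddata_profile(points) -> FixedDataProfile:
    """OLS quadratic fit of mean loss on log10(param_count).

    Requires >= 3 included points with distinct parameter counts; the
    fitted parabola must be convex (a > 0) for its minimum
    10**(-b / (2a)) to define an optimal model size.
    """
    included = [p for p in points if p.included_in_fit]
    if len(included) < 3:
        raise InsufficientDataError("need >= 3 included points")
    x = np.log10([p.param_count for p in included])
    if len(set(np.round(x, 12))) < 3:
        raise InsufficientDataError("need >= 3 distinct parameter counts")
    y = np.array([p.mean_loss for p in included], dtype=float)
    (a, b, c), r2 = _quadratic_ols(x, y)
    if a <= 0:
        raise NonConvexProfileError(f"fitted profile is not convex (a={a:.4g})")
    x_opt = -b / (2 * a)
    if not (x.min() - 1 <= x_opt <= x.max() + 1):
        warnings.warn(
            f"optimal size 10^{x_opt:.2f} lies well outside the fitted range",
            stacklevel=2,
        )
    return FixedDataProfile(
        data_scale_id=included[0].data_scale_id,
        a=float(a),
        b=float(b),
        c=float(c),
        r_squared=float(r2),
        optimal_param_count=float(10.0 ** x_opt),
        n_points=len(included),
    )


def fit_power_law(minima) -> PowerLaw:
    """Fit data_size = alpha * model_size**beta by OLS in log-log space.

    ``minima`` is a sequence of (optimal_param_count, data_size) pairs.
    """
    minima = list(minima)
    if len(minima) < 2:
        raise InsufficientDataError("need >= 2 minima")
    m = np.array([p[0] for p in minima], dtype=float)
    d = np.array([p[1] for p in minima], dtype=float)
    if (m <= 0).any() or (d <= 0).any():
        raise ValueError("sizes must be positive")
    x, y = np.log10(m), np.log10(d)
    X = np.column_stack([x, np.ones_like(x)])
    (beta, intercept), *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ np.array([beta, intercept])
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return PowerLaw(alpha=float(10.0 ** intercept), beta=float(beta), r_squared=float(r2))


def simulate_loss_grid(
    data_sizes,
    param_counts,
    alpha: float,
    beta: float,
    curvature: float = 1.0,
    base_loss: float = 2.0,
    noise_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
):
    """Synthesize a loss grid whose per-scale minima follow a known power law.

    For each data size D the loss over x = log10(M) is a parabola
    ``curvature * (x - x_opt(D))**2 + base_loss`` with
    ``x_opt(D) = log10((D / alpha) ** (1 / beta))``, i.e. the generating
    optima satisfy D = alpha * M**beta exactly. Gaussian noise of standard
    deviation ``noise_sd`` is added when an rng is supplied.
    """
    rng = rng or np.random.default_rng(0)
    points = []
    for si, D in enumerate(data_sizes):
        x_opt = np.log10((D / alpha) ** (1.0 / beta))
        for M in param_counts:
            x = np.log10(M)
            loss = curvature * (x - x_opt) ** 2 + base_loss
            if noise_sd > 0:
                loss += rng.normal(0.0, noise_sd)
            points.append(
                LossGridPoint(
                    param_count=int(M),
                    data_scale_id=f"scale_{si}",
                    data_size=int(D),
                    mean_loss=float(loss),
                )
            )
    return points


def fit_scaling_chain(points):
    """Full FixedData chain: grid -> per-scale profiles -> minima -> power law.

    Returns (profiles, power_law).
    """
    by_scale = {}
    for p in points:
        by_scale.setdefault(p.data_scale_id, []).append(p)
    profiles, minima = [], []
    for scale_id in sorted(by_scale):
        pts = exclude_outliers(by_scale[scale_id])
        profile = fit_fixeddata_profile(pts)
        profiles.append(profile)
        minima.append((profile.optimal_param_count, pts[0].data_size))
    return profiles, fit_power_law(minima)


def predict_optimal_data(model_size: float, law: PowerLaw) -> float:
    """Data-optimal training-set size (sequences) for a given model size."""
    if model_size <= 0:
        raise ValueError("model_size must be positive")
    return law.alpha * model_size ** law.beta


def predict_optimal_model(data_size: float, law: PowerLaw) -> float:
    """Model size for which a given data size is data-optimal (inverse law)."""
    if data_size <= 0:
        raise ValueError("data_size must be positive")
    if law.beta == 0:
        raise ZeroDivisionError("beta must be non-zero to invert the law")
    return (data_size / law.alpha) ** (1.0 / law.beta)
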