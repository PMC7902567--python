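"""Restricted cubic spline (natural spline) bases.

Continuous covariates — age, year of treatment, neutrophil/lymphocyte
ratio — rarely act linearly on log survival time, so the model expands
them on a restricted cubic spline basis: piecewise cubic between knots,
constrained to be linear beyond the boundary knots.  The construction is
Harrell's truncated-power parameterisation: with knots
``t_1 < ... < t_k`` the basis has ``k - 1`` columns, the raw covariate
plus ``k - 2`` restricted cubic terms, each scaled by
``(t_k - t_1)^2`` so all columns live on comparable scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["SplineBasis", "rcs_basis", "default_knots", "RestrictedCubicSpline"]

# Harrell's default quantiles for knot placement, per knot count.
_DEFAULT_QUANTILES = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
    6: (0.05, 0.23, 0.41, 0.59, 0.77, 0.95),
    7: (0.025, 0.1833, 0.3417, 0.50, 0.6583, 0.8167, 0.975),
}


@dataclass(frozen=True)
class SplineBasis:
    """Knot layout of one restricted cubic spline term.

    Attributes
    ----------
    knots : tuple of float
        Strictly increasing knot positions on the covariate's own scale.
    """

    knots: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        knots = tuple(float(k) for k in self.knots)
        if len(knots) < 3:
            raise ValueError(
                "a restricted cubic spline needs at least 3 knots; "
                "use the raw linear term instead"
            )
        if not np.all(np.diff(knots) > 0):
            raise ValueError(f"knots must be strictly increasing, got {knots}")
        object.__setattr__(self, "knots", knots)

    @property
    def n_basis(self) -> int:
        """Number of basis columns: linear term plus k - 2 cubic terms."""
        return len(self.knots) - 1

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        return rcs_basis(x, self.knots)


def rcs_basis(x: np.ndarray, knots) -> np.ndarray:
    """Evaluate the restricted cubic spline basis at ``x``.

    Parameters
    ----------
    x : array-like of shape (n,)
        Finite covariate values.
    knots : sequence of float
        At least 3 strictly increasing knot positions.

    Returns
    -------
    ndarray of shape (n, k - 1)
        Column 0 is ``x`` itself; columns ``1 .. k-2`` are the restricted
        cubic terms, identically zero for ``x`` at or below the first knot
        and linear in ``x`` beyond the last knot.
    """
    basis = SplineBasis(knots=tuple(knots))
    t = np.asarray(basis.knots, dtype=float)
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("x must be finite to evaluate a spline basis")
    k = len(t)
    scale = (t[-1] - t[0]) ** 2  # unit normalisation of the cubic terms

    def cube(u: np.ndarray) -> np.ndarray:
        return np.maximum(u, 0.0) ** 3

    cols = [x]
    denom = t[-1] - t[-2]
    for j in range(k - 2):
        term = (
            cube(x - t[j])
            - cube(x - t[-2]) * (t[-1] - t[j]) / denom
            + cube(x - t[-1]) * (t[-2] - t[j]) / denom
        )
        cols.append(term / scale)
    return np.column_stack(cols)


def default_knots(x: np.ndarray, k: int = 3) -> tuple[float, ...]:
    """Place ``k`` knots at Harrell's default quantiles of ``x``.

    For ``k = 3`` these are the 10th, 50th and 90th percentiles
    (linear-interpolation quantile estimator).  Raises if ties in ``x``
    collapse two knots onto the same value.
    """
    if k not in _DEFAULT_QUANTILES:
        raise ValueError(f"no default quantiles for k={k}; supported: {sorted(_DEFAULT_QUANTILES)}")
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < k:
        raise ValueError(f"need at least {k} finite observations to place {k} knots")
    knots = tuple(float(q) for q in np.quantile(x, _DEFAULT_QUANTILES[k]))
    if len(set(knots)) < k:
        raise ValueError(
            f"ties produce non-distinct knots {knots}; use fewer knots or the linear term"
        )
    return knots


class RestrictedCubicSpline(TransformerMixin, BaseEstimator):
    """Transformer expanding one column on a restricted cubic spline basis.

    Parameters
    ----------
    k : int, default 3
        Number of knots when `knots` is not given.
    knots : sequence of float, optional
        Explicit knot positions; overrides `k`.
    """

    def __init__(self, k: int = 3, knots=None):
        self.k = k
        self.knots = knots

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).reshape(-1)
        if self.knots is not None:
            self.basis_ = SplineBasis(knots=tuple(self.knots))
        else:
            self.basis_ = SplineBasis(knots=default_knots(x, self.k))
        self.n_features_in_ = 1
        return self

    def transform(self, X):
        check_is_fitted(self, "basis_")
        x = np.asarray(X, dtype=float).reshape(-1)
        return self.basis_.evaluate(x)

    def get_feature_names_out(self, input_features=None):
        name = "x" if input_features is None else str(input_features[0])
        return np.asarray(
            [name] + [f"{name}_rcs{j + 1}" for j in range(self.basis_.n_basis - 1)],
            dtype=object,
        )
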