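"""Sample-anchored orthogonal polynomial bases for age.

Curvilinear age models use orthogonal (orthonormal) polynomial scores of age
rather than raw powers, so that the linear, quadratic and cubic contributions
are separable and their coefficients stable.  The basis is anchored to the
analysis sample's age vector: the columns are orthonormal over that sample,
and the three-term recurrence constants are retained so the same polynomials
can be evaluated at arbitrary new ages (e.g. for fitted-curve plots).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin


def _as_column(X) -> np.ndarray:
    x = np.asarray(X, dtype=float)
    if x.ndim == 2 and x.shape[1] == 1:
        x = x[:, 0]
    if x.ndim != 1:
        raise ValueError("expected a 1-d age vector or a single-column matrix")
    if np.isnan(x).any():
        raise ValueError("age vector contains NaN")
    return x


class OrthogonalPolynomialBasis(TransformerMixin, BaseEstimator):
    """Orthonormal polynomial scores of a single covariate (age).

    Implements the Forsythe three-term recurrence: with ``p0 = 1``,

        p_j(x) = (x - alpha_j) p_{j-1}(x) - (nu_{j-1} / nu_{j-2}) p_{j-2}(x)

    where ``alpha_j`` and the squared norms ``nu_j`` are computed on the
    anchor sample.  Columns 1..degree are each divided by ``sqrt(nu_j)`` so
    that, on the anchor sample, every column sums to zero, has unit norm and
    is orthogonal to every other column (the same convention as R's
    ``poly()``).

    Parameters
    ----------
    degree : int
        Highest polynomial degree, between 1 and 3.

    Attributes
    ----------
    anchor_ages_ : ndarray
        The age vector the basis was fit on.
    columns_ : ndarray of shape (n, degree)
        Orthonormal scores at the anchor ages.
    alpha_, norm2_ : ndarray
        Recurrence constants; sufficient to evaluate the polynomials at new
        ages via :meth:`transform`.
    """

    def __init__(self, degree: int = 2):
        self.degree = degree

    def fit(self, X, y=None) -> "OrthogonalPolynomialBasis":
        x = _as_column(X)
        if not 1 <= int(self.degree) <= 3:
            raise ValueError(f"degree must be 1, 2 or 3, got {self.degree}")
        deg = int(self.degree)
        if np.unique(x).size < deg + 1:
            raise ValueError(
                f"need at least {deg + 1} distinct ages for a degree-{deg} "
                f"basis, got {np.unique(x).size}"
            )
        self.anchor_ages_ = x.copy()
        self.alpha_, self.norm2_ = self._recurrence_constants(x, deg)
        self.columns_ = self._evaluate(x)
        return self

    @staticmethod
    def _recurrence_constants(x: np.ndarray, deg: int):
        n = x.size
        raw = np.empty((n, deg + 1))
        raw[:, 0] = 1.0
        alpha = np.empty(deg)
        norm2 = np.empty(deg + 1)
        norm2[0] = float(n)
        for j in range(1, deg + 1):
            prev = raw[:, j - 1]
            alpha[j - 1] = float((x * prev**2).sum() / norm2[j - 1])
            p = (x - alpha[j - 1]) * prev
            if j >= 2:
                p = p - (norm2[j - 1] / norm2[j - 2]) * raw[:, j - 2]
            raw[:, j] = p
            norm2[j] = float((p**2).sum())
        return alpha, norm2

    def _evaluate(self, x: np.ndarray) -> np.ndarray:
        deg = int(self.degree)
        raw = np.empty((x.size, deg + 1))
        raw[:, 0] = 1.0
        for j in range(1, deg + 1):
            p = (x - self.alpha_[j - 1]) * raw[:, j - 1]
            if j >= 2:
                p = p - (self.norm2_[j - 1] / self.norm2_[j - 2]) * raw[:, j - 2]
            raw[:, j] = p
        return raw[:, 1:] / np.sqrt(self.norm2_[1:])

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "alpha_"):
            raise RuntimeError("basis is not fitted")
        return self._evaluate(_as_column(X))


def build_orthopoly(ages, degree: int) -> OrthogonalPolynomialBasis:
    """Fit an :class:`OrthogonalPolynomialBasis` on ``ages``."""
    return OrthogonalPolynomialBasis(degree=degree).fit(ages)
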