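"""Natural cubic spline basis for continuous covariates in Cox models.

A natural cubic spline with knots xi_1 < ... < xi_K is cubic between knots
and linear beyond the boundary knots. The K-1 non-constant basis columns are
the identity plus the usual truncated-power differences

    N_j(x) = d_j(x) - d_{K-1}(x),
    d_j(x) = [ (x - xi_j)_+^3 - (x - xi_K)_+^3 ] / (xi_K - xi_j),

so a fit with these columns spans the full natural-spline space without an
intercept (absorbed by the Cox baseline). Inputs are winsorised (clamped) to
the boundary knots before evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NaturalSpline"]


@dataclass(frozen=True)
class NaturalSpline:
    """Natural cubic spline basis with fixed knots (boundary knots included)."""

    knots: tuple  # ascending, length >= 3

    def __post_init__(self):
        k = np.asarray(self.knots, dtype=float)
        if len(k) < 3 or np.any(np.diff(k) <= 0):
            raise ValueError("need >= 3 strictly increasing knots")
        object.__setattr__(self, "knots", tuple(k))

    @classmethod
    def from_quantiles(cls, x, n_interior: int = 3, boundary=None) -> "NaturalSpline":
        """Interior knots at evenly spaced quantiles (25/50/75% for 3)."""
        x = np.asarray(x, dtype=float)
        qs = np.linspace(0, 100, n_interior + 2)[1:-1]
        interior = np.percentile(x, qs)
        if boundary is None:
            boundary = (x.min(), x.max())
        knots = np.unique(np.concatenate([[boundary[0]], interior, [boundary[1]]]))
        return cls(tuple(knots))

    @property
    def n_basis(self) -> int:
        return len(self.knots) - 1

    def basis(self, x) -> np.ndarray:
        """(n, K-1) design columns; x clamped to the boundary knots."""
        k = np.asarray(self.knots)
        x = np.clip(np.asarray(x, dtype=float), k[0], k[-1])
        K = len(k)

        def d(j):
            return (
                np.clip(x - k[j], 0, None) ** 3 - np.clip(x - k[-1], 0, None) ** 3
            ) / (k[-1] - k[j])

        dK1 = d(K - 2)
        cols = [x] + [d(j) - dK1 for j in range(K - 2)]
        return np.column_stack(cols)
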