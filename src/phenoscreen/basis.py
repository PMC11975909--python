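"""Control-anchored embedding-space scoring and SSMD assay quality.

The scoring axis runs from the centroid of the negative-control population
to the centroid of the positive-control population in embedding space. Each
cell (or image/well mean) decomposes into an "on basis" signed projection
along that axis and an "off basis" orthogonal residual distance; the
decomposition is Pythagorean: ||x - c_neg||^2 = on^2 + off^2.

Assay quality is the strictly standardized mean difference of on-basis
scores between the two control groups,

    beta = (mean_pos - mean_neg) / sqrt(var_pos + var_neg),

which is invariant under any common affine transform with positive scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


class DegenerateBasisError(ValueError):
    """Raised when positive and negative control centroids coincide."""


@dataclass(frozen=True)
class Basis:
    """Control axis: centroids, unit direction and length."""

    c_neg: np.ndarray
    c_pos: np.ndarray
    u: np.ndarray           # unit vector from c_neg toward c_pos
    d: float                # ||c_pos - c_neg||


@dataclass(frozen=True)
class BasisScore:
    on_basis_raw: float     # signed projection length from c_neg
    on_basis_norm: float    # 0 at c_neg, 1 at c_pos
    off_basis: float        # orthogonal residual norm, >= 0


@dataclass(frozen=True)
class BasisQCReport:
    """SSMD assay-quality report for one plate/assay."""

    beta: float
    n_neg: int
    n_pos: int
    mean_neg: float
    mean_pos: float
    var_neg: float
    var_pos: float
    threshold: float
    passed: bool
    degenerate: bool = False    # both variances zero; beta undefined (NaN)


def fit_basis(neg: np.ndarray, pos: np.ndarray) -> Basis:
    """Fit the control axis from negative/positive control embeddings.

    Centroids are arithmetic means over rows; each group needs >= 1 point
    (>= 2 recommended). Coincident centroids raise
    :class:`DegenerateBasisError`.
    """
    neg = np.atleast_2d(np.asarray(neg, dtype=np.float64))
    pos = np.atleast_2d(np.asarray(pos, dtype=np.float64))
    if neg.shape[0] < 1 or pos.shape[0] < 1:
        raise ValueError("each control group needs at least one point")
    if neg.shape[1] != pos.shape[1]:
        raise ValueError("control groups have different dimensions")
    c_neg = neg.mean(axis=0)
    c_pos = pos.mean(axis=0)
    delta = c_pos - c_neg
    d = float(np.linalg.norm(delta))
    if d < 1e-12:
        raise DegenerateBasisError("control centroids coincide; no axis")
    return Basis(c_neg=c_neg, c_pos=c_pos, u=delta / d, d=d)


def score(basis: Basis, x: np.ndarray) -> BasisScore:
    """On/off-basis decomposition of a single embedding."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape != basis.c_neg.shape:
        raise ValueError(
            f"dimension mismatch: x has shape {x.shape}, basis "
            f"{basis.c_neg.shape}")
    v = x - basis.c_neg
    on_raw = float(v @ basis.u)
    off = float(np.linalg.norm(v - on_raw * basis.u))
    return BasisScore(on_basis_raw=on_raw, on_basis_norm=on_raw / basis.d,
                      off_basis=off)


def score_many(basis: Basis, xs: np.ndarray) -> np.ndarray:
    """Vectorized scoring; returns an (n, 3) array of (raw, norm, off)."""
    xs = np.atleast_2d(np.asarray(xs, dtype=np.float64))
    v = xs - basis.c_neg
    on_raw = v @ basis.u
    resid = v - on_raw[:, None] * basis.u
    off = np.linalg.norm(resid, axis=1)
    return np.column_stack([on_raw, on_raw / basis.d, off])


def ssmd(neg_scores, pos_scores, threshold: float = 2.0,
         population_variance: bool = False) -> BasisQCReport:
    """Strictly standardized mean difference of two score populations.

    Sample variances (denominator n-1) by default; ``population_variance``
    switches to denominator n. If both variances are zero the report is
    flagged degenerate and beta is NaN.
    """
    a = np.asarray(neg_scores, dtype=np.float64)
    b = np.asarray(pos_scores, dtype=np.float64)
    ddof = 0 if population_variance else 1
    if a.size < ddof + 1 or b.size < ddof + 1:
        raise ValueError("each group needs at least two values")
    var_a = float(a.var(ddof=ddof))
    var_b = float(b.var(ddof=ddof))
    mean_a, mean_b = float(a.mean()), float(b.mean())
    if var_a + var_b <= 0.0:
        return BasisQCReport(beta=math.nan, n_neg=a.size, n_pos=b.size,
                             mean_neg=mean_a, mean_pos=mean_b,
                             var_neg=var_a, var_pos=var_b,
                             threshold=threshold, passed=False, degenerate=True)
    beta = (mean_b - mean_a) / math.sqrt(var_a + var_b)
    return BasisQCReport(beta=beta, n_neg=a.size, n_pos=b.size,
                         mean_neg=mean_a, mean_pos=mean_b,
                         var_neg=var_a, var_pos=var_b,
                         threshold=threshold, passed=beta >= threshold)


def ssmd_from_params(mean_neg: float, sd_neg: float,
                     mean_pos: float, sd_pos: float) -> float:
    """SSMD from exact population parameters (no sampling)."""
    denom = math.sqrt(sd_neg ** 2 + sd_pos ** 2)
    if denom == 0.0:
        return math.nan
    return (mean_pos - mean_neg) / denom
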