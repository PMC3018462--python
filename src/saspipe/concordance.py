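"""Array-vs-qPCR fold-change concordance: Pearson r on log-transformed folds.

Fold changes arrive as signed ratios (the field convention: +2 means 2-fold
up, -4 means 4-fold down). The sign-preserving log2 transform maps a signed
ratio x to sign(x) * log2(|x|), so +2 -> +1, -4 -> -2, +1 -> 0, after which
the standard product-moment correlation and its two-sided p-value (t
transform with n - 2 degrees of freedom) are computed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special


@dataclass
class CorrelationResult:
    r: float
    r_squared: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError("r out of range")


def log_transform_folds(folds) -> np.ndarray:
    """Sign-preserving log2 of signed fold ratios, order preserved.

    A |fold| below 1 is accepted (it maps into the (-1, 1) band) but warned
    about, since fold-change conventions normally keep |ratio| >= 1.
    """
    x = np.asarray(folds, dtype=float)
    if (x == 0).any():
        raise ValueError("fold changes must be nonzero")
    if (np.abs(x) < 1).any():
        warnings.warn("fold changes with |ratio| < 1 encountered", stacklevel=2)
    return np.sign(x) * np.log2(np.abs(x))


def pearson_with_p(x, y) -> CorrelationResult:
    """Pearson product-moment r with a two-sided p from the t transform.

    t = r * sqrt((n - 2) / (1 - r^2)) with n - 2 df. Requires n >= 3 and
    non-constant vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs for a correlation p-value")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = math.sqrt(float(dx @ dx))
    sy = math.sqrt(float(dy @ dy))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("correlation undefined for a constant vector")
    r = float(np.clip((dx @ dy) / (sx * sy), -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * special.stdtr(n - 2, -abs(t)))
    return CorrelationResult(r=r, r_squared=r * r, p_value=p, n=n)


def concordance_from_pairs(array_folds, qpcr_folds) -> CorrelationResult:
    """Log-transform both signed fold vectors, then correlate."""
    return pearson_with_p(log_transform_folds(array_folds), log_transform_folds(qpcr_folds))
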