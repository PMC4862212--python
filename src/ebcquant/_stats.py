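"""Shared statistical conventions: signed fold changes and t-tests.

All three assay pipelines report ratios with the signed convention used
throughout comparative proteomics tables: increases as salt/control,
decreases as the negative reciprocal, so every finite value has
magnitude >= 1.  Condition-exclusive features are reported with the
``INF``/``ZERO`` tokens rather than an arbitrary numeric stand-in.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as _sps

#: token for features detected only under salt (control mean is zero)
INF = "INF"
#: token for features detected only in control (salt mean is zero)
ZERO = "ZERO"
#: token for features with zero signal on both sides
UNDEFINED = "UNDEFINED"

FLAG_STRONG = "**"
FLAG_WEAK = "*"
FLAG_NS = "NS"


def signed_ratio(ratio: float) -> float:
    """Map a positive ratio onto the signed fold-change scale.

    ``r >= 1`` stays ``r``; ``r < 1`` becomes ``-1/r`` so that a halving
    is reported as -2 rather than 0.5.
    """
    if ratio <= 0 or not np.isfinite(ratio):
        raise ValueError(f"signed_ratio requires a finite positive ratio, got {ratio!r}")
    return float(ratio) if ratio >= 1.0 else float(-1.0 / ratio)


def unsign_ratio(fc: float) -> float:
    """Inverse of :func:`signed_ratio`: back to a plain positive ratio."""
    if fc == 0:
        raise ValueError("signed fold changes are never 0")
    return float(fc) if fc >= 1.0 else float(-1.0 / fc)


def fold_change(control_values, salt_values) -> float | str:
    """Signed fold change of mean(salt)/mean(control), with exclusivity tokens.

    Returns ``INF`` when control is all zero but salt is not, ``ZERO`` for
    the converse, and ``UNDEFINED`` when both sides are all zero.
    """
    control = np.asarray(control_values, dtype=float)
    salt = np.asarray(salt_values, dtype=float)
    if control.size == 0 or salt.size == 0:
        raise ValueError("fold_change needs at least one replicate per condition")
    mc, ms = control.mean(), salt.mean()
    if mc == 0 and ms == 0:
        return UNDEFINED
    if mc == 0:
        return INF
    if ms == 0:
        return ZERO
    return signed_ratio(ms / mc)


def ttest_equal_var(a: np.ndarray, b: np.ndarray, axis: int = -1) -> np.ndarray:
    """Two-sample two-tailed Student's t-test (pooled variance), vectorised.

    Degenerate rows where both groups have zero variance are resolved by
    convention: equal means -> p = 1, unequal means -> p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.shape[axis], b.shape[axis]
    if na < 2 or nb < 2:
        raise ValueError("need >=2 replicates per condition")
    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # near-constant rows trigger scipy's precision-loss warning; the
        # degenerate cases are resolved by the convention below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = _sps.ttest_ind(a, b, axis=axis, equal_var=True)
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = (a.var(axis=axis) == 0) & (b.var(axis=axis) == 0)
    if np.any(degenerate):
        equal = np.isclose(a.mean(axis=axis), b.mean(axis=axis))
        p = np.where(degenerate & equal, 1.0, p)
        p = np.where(degenerate & ~equal, 0.0, p)
    # zero variance in one group only: scipy yields a finite p unless the
    # pooled variance vanished, which the branch above already covered
    return p


def significance_flag(p: float, alpha_weak: float = 0.05, alpha_strong: float = 0.01) -> str:
    """Map a p-value to the two-tier star notation (``**``, ``*``, ``NS``)."""
    if not np.isfinite(p):
        return FLAG_NS
    if p <= alpha_strong:
        return FLAG_STRONG
    if p <= alpha_weak:
        return FLAG_WEAK
    return FLAG_NS
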