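"""Donor-paired group comparisons for clot volumes and resistance trajectories.

Every donor runs every chamber configuration, so condition effects are
assessed within donors.  Inference uses sign-flip permutation tests on the
within-donor differences: under the null of no condition effect, each
donor's difference is symmetric about zero, so flipping its sign is an
exchangeable transformation.  This replaces covariance-structured mixed
models with an exact, assumption-light procedure adequate for paired effect
directions.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupComparisonResult",
    "TrendResult",
    "paired_permutation_test",
    "bonferroni_adjust",
    "trend_effect",
]

_TIE_EPS = 1e-12


@dataclass(frozen=True)
class GroupComparisonResult:
    """Outcome of a paired two-group comparison.

    ``statistic`` is the mean within-donor difference (group A minus
    group B), in the units of the input.  ``p_value`` is two-sided; for
    sampled permutations it carries the +1 correction and can never be 0.
    """

    statistic: float
    p_value: float
    n_donors: int
    n_permutations: int
    exact: bool
    seed: int | None = None
    labels: tuple[str, str] = ("A", "B")

    def __post_init__(self) -> None:
        assert 0.0 < self.p_value <= 1.0


def paired_permutation_test(
    values_a,
    values_b,
    n_perm: int = 10_000,
    seed: int = 0,
    exact: bool | None = None,
    labels: tuple[str, str] = ("A", "B"),
) -> GroupComparisonResult:
    """Two-sided sign-flip permutation test on within-donor differences.

    ``values_a`` and ``values_b`` are aligned per donor (donor i contributes
    ``values_a[i] - values_b[i]``); a donor missing from either group is an
    error in a paired design.  The null distribution flips each donor's
    difference sign independently.  With ``exact`` (the default whenever
    2**n_donors <= n_perm) all sign patterns are enumerated and
    p = #{|T*| >= |T|} / 2**n; otherwise ``n_perm`` random flips give
    p = (1 + #{|T*| >= |T|}) / (n_perm + 1), so p is never exactly zero.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.ndim != 1 or b.ndim != 1:
        raise ValueError("group values must be one-dimensional")
    if a.shape != b.shape:
        raise ValueError(
            f"paired design requires every donor in both groups "
            f"({a.size} vs {b.size} values)"
        )
    if a.size == 0:
        raise ValueError("no donors")
    if np.any(np.isnan(a)) or np.any(np.isnan(b)):
        raise ValueError("missing (NaN) donor values break the pairing")
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")

    diffs = a - b
    n = diffs.size
    t_obs = diffs.mean()

    if exact is None:
        exact = 2**n <= n_perm
    if exact:
        signs = np.array(list(product((1.0, -1.0), repeat=n)))
        t_null = signs @ diffs / n
        count = int(np.sum(np.abs(t_null) >= abs(t_obs) - _TIE_EPS))
        p = count / len(signs)
        n_used = len(signs)
        used_seed = None
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice((1.0, -1.0), size=(n_perm, n))
        t_null = signs @ diffs / n
        count = int(np.sum(np.abs(t_null) >= abs(t_obs) - _TIE_EPS))
        p = (1 + count) / (n_perm + 1)
        n_used = n_perm
        used_seed = seed
    return GroupComparisonResult(
        statistic=float(t_obs),
        p_value=float(p),
        n_donors=n,
        n_permutations=n_used,
        exact=bool(exact),
        seed=used_seed,
        labels=labels,
    )


def bonferroni_adjust(p_values) -> np.ndarray:
    """Bonferroni family-wise correction: min(1, m * p) over m comparisons."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return np.minimum(1.0, p * p.size)


@dataclass(frozen=True)
class TrendResult:
    """Monotone association between ordered condition levels and summaries."""

    correlation: float  # Kendall tau for >= 3 levels, +/-1 or 0 for 2 levels
    sign: int
    n_levels: int


def trend_effect(condition_levels, summaries) -> TrendResult:
    """Direction of a monotone dose-response across ordered condition levels.

    With three or more levels, Kendall's tau between level and summary; with
    exactly two levels, the sign of the difference.  Used to check recovered
    effect directions (e.g. more clot at higher packing density, less at
    higher velocity).
    """
    x = np.asarray(condition_levels, dtype=float)
    y = np.asarray(summaries, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("levels and summaries must be matching 1-D sequences")
    if x.size < 2:
        raise ValueError("need at least two condition levels")
    if x.size == 2:
        d = (y[np.argmax(x)] - y[np.argmin(x)])
        corr = float(np.sign(d))
        return TrendResult(correlation=corr, sign=int(np.sign(d)), n_levels=2)
    tau = sps.kendalltau(x, y).statistic
    tau = 0.0 if np.isnan(tau) else float(tau)
    return TrendResult(correlation=tau, sign=int(np.sign(tau)), n_levels=int(x.size))
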