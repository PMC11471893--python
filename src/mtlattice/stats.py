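"""Two-group comparison of lattice-spacing cohorts.

Spacing distributions from different conditions (untreated vs drug-treated
cells, decorated vs undecorated microtubules, ...) are compared with an
unpaired two-tailed t-statistic permutation test: group labels are permuted
uniformly at random (10,000 iterations by default) and the p-value is the
fraction of permutations with |t| at least as extreme as observed, with the
add-one correction p = (count + 1) / (n_iter + 1) so a Monte-Carlo p is
never exactly zero.  For small cohorts the null can instead be enumerated
exhaustively over all label splits (p = count / n_splits).

The pooled-variance t is the default permutation statistic; under label
permutation the test is exact for any statistic, and Welch's t is available
as a switch.  Cohort summaries (fraction of spacings in the compacted band,
quartiles, extremes) back violin-plot style reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Optional

import numpy as np

__all__ = [
    "PermutationTestResult",
    "CohortSummary",
    "t_statistic",
    "permutation_test",
    "summarize_cohort",
    "plot_spacing_violins",
]


@dataclass
class PermutationTestResult:
    t_obs: float
    p_value: float
    n_iter: int
    n_exceed: int
    exhaustive: bool
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0 < self.p_value <= 1:
            raise ValueError(f"p_value out of (0, 1]: {self.p_value}")


@dataclass
class CohortSummary:
    n: int
    n_compacted: int
    fraction_compacted: float
    quartiles: tuple      # (q1, median, q3) in Å
    min: float
    max: float
    threshold: float


def _validate_groups(a, b, min_n: int = 2) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if len(a) < min_n or len(b) < min_n:
        raise ValueError(f"each group needs >= {min_n} values, got "
                         f"{len(a)}, {len(b)}")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite values in input groups")
    return a, b


def t_statistic(a, b, pooled: bool = True) -> float:
    """Unpaired two-sample t (pooled variance by default).

    Antisymmetric under group swap.  With zero pooled variance the
    statistic is 0 when the means are equal and an error otherwise.
    """
    a, b = _validate_groups(a, b)
    na, nb = len(a), len(b)
    ma, mb = a.mean(), b.mean()
    if pooled:
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) \
            / (na + nb - 2)
        denom = np.sqrt(sp2 * (1 / na + 1 / nb))
    else:  # Welch
        denom = np.sqrt(a.var(ddof=1) / na + b.var(ddof=1) / nb)
    if denom == 0:
        if ma == mb:
            return 0.0
        raise ValueError("zero variance with unequal means: t undefined")
    return float((ma - mb) / denom)


def _t_many(groups_a: np.ndarray, groups_b: np.ndarray,
            pooled: bool) -> np.ndarray:
    """Vectorised t over rows of permuted groups (zero-variance rows -> 0)."""
    na = groups_a.shape[1]
    nb = groups_b.shape[1]
    ma = groups_a.mean(axis=1)
    mb = groups_b.mean(axis=1)
    va = groups_a.var(axis=1, ddof=1)
    vb = groups_b.var(axis=1, ddof=1)
    if pooled:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        denom = np.sqrt(sp2 * (1 / na + 1 / nb))
    else:
        denom = np.sqrt(va / na + vb / nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / denom
    return np.where(denom == 0, 0.0, t)


def permutation_test(a, b, n_iter: int = 10_000,
                     seed: Optional[int] = None,
                     mode: str = "mc",
                     exhaustive_cap: int = 200_000,
                     pooled: bool = True) -> PermutationTestResult:
    """Unpaired two-tailed t-based permutation test.

    Parameters
    ----------
    mode : {"mc", "exhaustive", "auto"}
        Monte-Carlo label permutation (default; requires ``seed``),
        exhaustive enumeration of all C(n_a + n_b, n_a) splits, or
        exhaustive-when-affordable (split count <= ``exhaustive_cap``).
    pooled : bool
        Pooled-variance t (default) or Welch's t as the statistic.

    The two-tailed criterion is ``|t_perm| >= |t_obs|`` (with a 1e-12
    relative tolerance against floating-point ties).  Monte-Carlo p-values
    use the add-one correction (count + 1) / (n_iter + 1); exhaustive
    p-values are count / n_splits (the observed split is in the
    enumeration, so p > 0).
    """
    a, b = _validate_groups(a, b)
    na, nb = len(a), len(b)
    if na + nb < 4:
        raise ValueError("combined sample size must be >= 4")
    if mode not in ("mc", "exhaustive", "auto"):
        raise ValueError(f"mode: unknown mode {mode!r}")
    t_obs = t_statistic(a, b, pooled=pooled)
    thresh = abs(t_obs) - 1e-12 * max(1.0, abs(t_obs))
    pool = np.concatenate([a, b])
    n = na + nb

    n_splits = comb(n, na)
    if mode == "auto":
        mode = "exhaustive" if n_splits <= exhaustive_cap else "mc"

    if mode == "exhaustive":
        if n_splits > exhaustive_cap:
            raise ValueError(f"{n_splits} label splits exceed the cap "
                             f"{exhaustive_cap}")
        idx_a = np.array(list(combinations(range(n), na)))
        sel = np.zeros((n_splits, n), dtype=bool)
        sel[np.arange(n_splits)[:, None], idx_a] = True
        ga = pool[np.nonzero(sel)[1]].reshape(n_splits, na)
        gb = pool[np.nonzero(~sel)[1]].reshape(n_splits, nb)
        t_perm = _t_many(ga, gb, pooled)
        n_exceed = int(np.sum(np.abs(t_perm) >= thresh))
        return PermutationTestResult(t_obs=t_obs,
                                     p_value=n_exceed / n_splits,
                                     n_iter=n_splits, n_exceed=n_exceed,
                                     exhaustive=True, seed=None)

    if n_iter < 1:
        raise ValueError("n_iter: must be >= 1")
    if seed is None:
        raise ValueError("seed: required in Monte-Carlo mode")
    rng = np.random.default_rng(seed)
    n_exceed = 0
    chunk = max(1, min(n_iter, 20_000_000 // max(n, 1)))
    done = 0
    while done < n_iter:
        m = min(chunk, n_iter - done)
        order = np.argsort(rng.random((m, n)), axis=1)
        perm = pool[order]
        t_perm = _t_many(perm[:, :na], perm[:, na:], pooled)
        n_exceed += int(np.sum(np.abs(t_perm) >= thresh))
        done += m
    return PermutationTestResult(t_obs=t_obs,
                                 p_value=(n_exceed + 1) / (n_iter + 1),
                                 n_iter=n_iter, n_exceed=n_exceed,
                                 exhaustive=False, seed=seed)


def summarize_cohort(spacings, threshold: float = 41.3) -> CohortSummary:
    """Cohort summary: fraction compacted, quartiles, extremes.

    "Compacted" means spacing < threshold (the compacted/expanded band
    midpoint, default 41.3 Å).  Quartiles use the linear-interpolation
    convention of ``numpy.percentile``.
    """
    s = np.asarray(spacings, dtype=float).ravel()
    if len(s) == 0:
        raise ValueError("empty cohort")
    if not np.all(np.isfinite(s)):
        raise ValueError("non-finite spacings")
    n_comp = int(np.sum(s < threshold))
    q1, med, q3 = np.percentile(s, [25, 50, 75])
    return CohortSummary(n=len(s), n_compacted=n_comp,
                         fraction_compacted=n_comp / len(s),
                         quartiles=(float(q1), float(med), float(q3)),
                         min=float(s.min()), max=float(s.max()),
                         threshold=threshold)


def plot_spacing_violins(cohorts: dict, grid=None, ax=None):
    """Basic violin rendering of spacing cohorts (Å), optional grid lines.

    ``cohorts`` maps label -> array of spacings; ``grid`` (if given) draws
    the attainable reciprocal-space spacings as horizontal lines.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.5 * max(len(cohorts), 2), 4))
    labels = list(cohorts)
    data = [np.asarray(cohorts[k], dtype=float) for k in labels]
    ax.violinplot(data, showmedians=True)
    if grid is not None:
        for g in np.asarray(grid, dtype=float):
            ax.axhline(g, color="0.8", lw=0.5, zorder=0)
    ax.set_xticks(np.arange(1, len(labels) + 1), labels)
    ax.set_ylabel("lattice spacing (Å)")
    return ax
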