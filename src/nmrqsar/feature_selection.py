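"""Descriptor-subset selection.

Three selectors are provided:

* correlation-based subset selection: maximize the merit
  ``k * mean|r_cf| / sqrt(k + k*(k-1) * mean|r_ff|)`` with best-first
  (with backtracking), greedy forward, or exhaustive search;
* stepwise least-squares elimination: repeatedly drop the feature with
  the smallest absolute standardized coefficient while the AIC does not
  worsen;
* top-N selection by a supplied importance vector.

All selections are deterministic; ties break to the lower feature index.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np


class SelectionError(ValueError):
    pass


@dataclass
class SelectionResult:
    selected: list[int]              # 0-based feature indices, selection order
    trace: list[float] = field(default_factory=list)  # per-step criterion values
    strategy: str = ""

    def __post_init__(self) -> None:
        if len(set(self.selected)) != len(self.selected):
            raise SelectionError("selected indices must be unique")

    def to_csv(self, path, names=None) -> None:
        import pandas as pd

        rows = []
        for rank, idx in enumerate(self.selected, start=1):
            rows.append(
                {
                    "rank": rank,
                    "index": idx,
                    "name": names[idx] if names is not None else str(idx),
                    "criterion": self.trace[rank - 1] if rank - 1 < len(self.trace) else float("nan"),
                }
            )
        pd.DataFrame(rows, columns=["rank", "index", "name", "criterion"]).to_csv(
            path, index=False
        )


# ---------------------------------------------------------------------------
# correlation-based subset selection


def cfs_merit(subset, r_cf, r_ff) -> float:
    """Merit of a feature subset from absolute correlations.

    ``r_cf`` holds feature-target correlations (length p); ``r_ff`` the
    p x p feature-feature correlation matrix.  For k features with mean
    absolute correlations rcf and rff the merit is
    ``k * rcf / sqrt(k + k*(k-1) * rff)``; k = 1 reduces to |r_cf|.
    """
    subset = list(subset)
    if not subset:
        raise SelectionError("merit of an empty subset is undefined")
    r_cf = np.abs(np.asarray(r_cf, dtype=float))
    r_ff = np.abs(np.asarray(r_ff, dtype=float))
    if (r_cf > 1 + 1e-12).any() or (r_ff > 1 + 1e-12).any():
        raise SelectionError("correlations must lie in [-1, 1]")
    k = len(subset)
    rcf = float(r_cf[subset].mean())
    if k == 1:
        return rcf
    idx = np.asarray(subset)
    pairs = r_ff[np.ix_(idx, idx)]
    rff = float((pairs.sum() - np.trace(pairs)) / (k * (k - 1)))
    return k * rcf / math.sqrt(k + k * (k - 1) * rff)


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation; 0 for a constant column (no linear association)."""
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def correlations(X, y) -> tuple[np.ndarray, np.ndarray]:
    """Feature-target and feature-feature Pearson correlations.

    A binary 0/1 target yields the point-biserial correlation, which is
    Pearson on the 0/1 encoding.  Constant columns get correlation 0.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0:
        raise SelectionError("constant target")
    p = X.shape[1]
    r_cf = np.array([_safe_corr(X[:, j], y) for j in range(p)])
    r_ff = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            r_ff[i, j] = r_ff[j, i] = _safe_corr(X[:, i], X[:, j])
    return r_cf, r_ff


def _expansions(subset: frozenset, p: int):
    for j in range(p):
        if j not in subset:
            yield frozenset(subset | {j})


def cfs_search(
    X,
    y,
    strategy: str = "best_first",
    max_stale: int = 5,
    backtracking: bool = True,
) -> SelectionResult:
    """Search for the merit-maximal feature subset.

    ``best_first``: forward best-first search over subsets with
    backtracking, terminating after ``max_stale`` consecutive expansions
    that fail to improve the best merit.  With ``backtracking=False`` it
    degrades to plain forward selection (linear forward selection).
    ``greedy_stepwise``: forward selection, stop at the first
    non-improving step.  ``exhaustive``: all non-empty subsets (p <= 20),
    intended as a small-p oracle.

    If no single feature has positive merit the selection is empty.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise SelectionError("X must be 2-D with at least 2 features")
    r_cf, r_ff = correlations(X, y)
    p = X.shape[1]

    def merit(s: frozenset) -> float:
        return cfs_merit(sorted(s), r_cf, r_ff) if s else 0.0

    if strategy == "exhaustive":
        if p > 20:
            raise SelectionError("exhaustive search is limited to 20 features")
        best, best_m = frozenset(), 0.0
        for k in range(1, p + 1):
            for combo in itertools.combinations(range(p), k):
                m = merit(frozenset(combo))
                if m > best_m + 1e-12:
                    best, best_m = frozenset(combo), m
        return SelectionResult(sorted(best), [best_m], "exhaustive")

    if strategy == "greedy_stepwise":
        current, current_m = frozenset(), 0.0
        order, trace = [], []
        while True:
            gains = [(merit(frozenset(current | {j})), j) for j in range(p) if j not in current]
            if not gains:
                break
            m, j = max(gains, key=lambda t: (t[0], -t[1]))
            if m <= current_m + 1e-12:
                break
            current, current_m = frozenset(current | {j}), m
            order.append(j)
            trace.append(m)
        return SelectionResult(order, trace, "greedy_stepwise")

    if strategy != "best_first":
        raise SelectionError(f"unknown strategy {strategy!r}")

    # best-first over the subset lattice (forward expansions only)
    open_list: list[tuple[float, frozenset]] = [(0.0, frozenset())]
    closed: set[frozenset] = set()
    best, best_m = frozenset(), 0.0
    stale = 0
    while open_list and stale < max_stale:
        open_list.sort(key=lambda t: (-t[0], sorted(t[1])))
        m, subset = open_list.pop(0)
        if subset in closed:
            continue
        closed.add(subset)
        improved = False
        for child in _expansions(subset, p):
            if child in closed:
                continue
            cm = merit(child)
            open_list.append((cm, child))
            if cm > best_m + 1e-12:
                best, best_m = child, cm
                improved = True
        if improved:
            stale = 0
        else:
            stale += 1
        if not backtracking:
            # keep only children of the node just expanded: plain forward path
            open_list = [t for t in open_list if t[1] > subset]
    return SelectionResult(
        sorted(best), [best_m], "best_first" if backtracking else "linear_forward"
    )


# ---------------------------------------------------------------------------
# stepwise least-squares elimination with AIC stopping


def _fit_ols(X: np.ndarray, y: np.ndarray, subset: list[int]) -> tuple[np.ndarray, float]:
    """Least-squares fit of y on X[:, subset] + intercept; returns
    (coefficients without intercept, RSS)."""
    n = X.shape[0]
    design = np.column_stack([np.ones(n), X[:, subset]]) if subset else np.ones((n, 1))
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return coef[1:], float(resid @ resid)


def aic_ls(n: int, rss: float, n_params: int, rss_floor: float = 1e-300) -> float:
    """Least-squares AIC: n*ln(RSS/n) + 2*(p+1).

    ``rss_floor`` keeps the log finite for (near-)interpolating fits and
    makes all numerically perfect fits share one RSS, so they compare by
    parameter count alone instead of by machine-epsilon noise."""
    rss = max(rss, rss_floor)
    return n * math.log(rss / n) + 2.0 * (n_params + 1)


def m5_select(X, y, ridge: float = 0.0) -> SelectionResult:
    """Stepwise backward elimination of least-squares features.

    Starting from the full model, each step refits and removes the feature
    with the smallest absolute standardized coefficient
    (|coef| * sd(feature) / sd(target)); elimination continues while the
    AIC of the reduced model is no worse, and stops (keeping the current
    model) at the first AIC increase.  The trace records the AIC after
    each accepted step.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if np.ptp(y) == 0:
        raise SelectionError("constant target")
    sd_y = y.std()
    sd_x = X.std(axis=0)
    usable = [j for j in range(p) if sd_x[j] > 0]
    if len(usable) < 2:
        raise SelectionError("need at least 2 non-constant features")
    if n <= len(usable) and ridge <= 0:
        raise SelectionError(
            f"underdetermined fit (n={n} <= p={len(usable)}); pass ridge > 0"
        )

    def fit(subset: list[int]) -> tuple[np.ndarray, float]:
        if ridge > 0 and subset:
            design = np.column_stack([np.ones(n), X[:, subset]])
            penalty = ridge * np.eye(design.shape[1])
            penalty[0, 0] = 0.0
            coef = np.linalg.solve(design.T @ design + penalty, design.T @ y)
            resid = y - design @ coef
            return coef[1:], float(resid @ resid)
        return _fit_ols(X, y, subset)

    rss_floor = n * (1e-8 * sd_y) ** 2
    current = list(usable)
    _, rss = fit(current)
    current_aic = aic_ls(n, rss, len(current), rss_floor)
    trace = [current_aic]
    while current:
        coef, _ = fit(current)
        std_coef = np.abs(coef) * sd_x[current] / sd_y
        drop_pos = int(np.argmin(std_coef))  # ties -> lowest position -> lowest index
        candidate = current[:drop_pos] + current[drop_pos + 1 :]
        _, rss_c = fit(candidate)
        cand_aic = aic_ls(n, rss_c, len(candidate), rss_floor)
        if cand_aic <= current_aic:
            current, current_aic = candidate, cand_aic
            trace.append(cand_aic)
        else:
            break
    return SelectionResult(sorted(current), trace, "m5")


# ---------------------------------------------------------------------------
# importance-based top-N


def rf_top_n(importances, n: int) -> SelectionResult:
    """Indices of the ``n`` largest importances; ties break to the lower
    index.  Returned in decreasing-importance order."""
    importances = np.asarray(importances, dtype=float)
    if n < 1:
        raise SelectionError(f"n must be >= 1, got {n}")
    if n > importances.size:
        raise SelectionError(f"n={n} exceeds the number of features ({importances.size})")
    # stable sort on negated values: equal importances keep ascending index
    order = np.argsort(-importances, kind="stable")[:n]
    return SelectionResult(
        [int(i) for i in order], [float(importances[i]) for i in order], "rf_top_n"
    )
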