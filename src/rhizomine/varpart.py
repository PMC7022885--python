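"""Variance partitioning of a multivariate response by redundancy analysis.

A multivariate response (here: a host expression matrix, samples x
genes) is explained by up to four explanatory sets (community profiles,
functional profiles, design factors).  Each set's redundancy-analysis
R^2 is bias-adjusted with Ezekiel's formula, and inclusion-exclusion
over the adjusted R^2 of all unions splits the explained variance into
unique and shared fractions.  Shared fractions are not testable; unique
fractions are tested by partial RDA with permutation of response rows,
and candidate variables can be screened by forward selection with the
double stopping criterion (permutation p-value below alpha AND the
cumulative adjusted R^2 staying below the global model's).

Adjusted-R^2 fractions can legitimately be slightly negative; they are
reported as-is, never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd

_LETTERS = "abcd"


@dataclass
class ExplanatorySet:
    """A named block of explanatory variables (samples x variables).

    Factors must arrive dummy-coded (one level dropped); constant
    columns are rejected because they carry no variance to attribute.
    """

    name: str
    matrix: pd.DataFrame

    def __post_init__(self):
        values = self.matrix.to_numpy(dtype=float)
        if values.shape[1] == 0:
            raise ValueError(f"explanatory set {self.name!r} has no columns")
        if (values.std(axis=0) == 0).any():
            constant = [
                c for c, s in zip(self.matrix.columns, values.std(axis=0)) if s == 0
            ]
            raise ValueError(
                f"constant columns in set {self.name!r}: {constant}"
            )


def factor_set(name: str, labels: pd.Series) -> ExplanatorySet:
    """Dummy-code a categorical factor, dropping the first level."""
    dummies = pd.get_dummies(labels, prefix=name, drop_first=True, dtype=float)
    return ExplanatorySet(name=name, matrix=dummies)


def hellinger(values: pd.DataFrame) -> pd.DataFrame:
    """Hellinger transform of a samples x variables abundance matrix:
    square root of row-relative abundances.  Downweights large counts
    so Euclidean-based ordination behaves sensibly on abundances."""
    totals = values.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("Hellinger transform needs positive row sums")
    return np.sqrt(values.div(totals, axis=0))


def _as_matrix(x) -> np.ndarray:
    if isinstance(x, ExplanatorySet):
        x = x.matrix
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr


def _fit_stats(y: np.ndarray, x: np.ndarray) -> tuple[float, float, int]:
    """(SS_fit, SS_total, rank) of the least-squares projection of the
    column-centered response on the column-centered design."""
    yc = y - y.mean(axis=0)
    xc = x - x.mean(axis=0)
    ss_total = float(np.sum(yc**2))
    rank = int(np.linalg.matrix_rank(xc)) if xc.size else 0
    if rank == 0:
        return 0.0, ss_total, 0
    coef, *_ = np.linalg.lstsq(xc, yc, rcond=None)
    fitted = xc @ coef
    return float(np.sum(fitted**2)), ss_total, rank


def rda_r2(y, x) -> tuple[float, float]:
    """Redundancy-analysis R^2 and Ezekiel-adjusted R^2.

    R^2 is the fraction of the response's total (centered) sum of
    squares captured by the least-squares projection on the design;
    the adjustment is ``1 - (1 - R^2) (n - 1)/(n - p - 1)`` with ``p``
    the design rank.
    """
    y = _as_matrix(y)
    x = _as_matrix(x)
    n = y.shape[0]
    if x.shape[0] != n:
        raise ValueError("response and design have different sample counts")
    ss_fit, ss_total, rank = _fit_stats(y, x)
    if ss_total == 0:
        raise ValueError("response has no variance")
    if n - rank - 1 <= 0:
        raise ValueError(
            f"design rank {rank} leaves no residual degrees of freedom (n={n})"
        )
    r2 = ss_fit / ss_total
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - rank - 1)
    return r2, adj


def anova_rda(
    y, x, n_perm: int = 999, seed: Optional[int] = None
) -> tuple[float, float]:
    """Permutational significance of an RDA model.

    pseudo-F = (SS_fit/p) / (SS_res/(n-p-1)); the null distribution
    comes from permuting response rows, and the p-value carries the
    +1 correction, so it is never below 1/(n_perm+1).

    Returns (pseudo_F, p).
    """
    y = _as_matrix(y)
    x = _as_matrix(x)
    n = y.shape[0]
    ss_fit, ss_total, rank = _fit_stats(y, x)
    if n - rank - 1 <= 0:
        raise ValueError("no residual degrees of freedom")

    def f_stat(fit: float, total: float) -> float:
        residual = max(total - fit, 0.0)  # round-off can dip below zero
        if residual == 0.0:
            return np.inf
        return (fit / rank) / (residual / (n - rank - 1))

    f_obs = f_stat(ss_fit, ss_total)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        ss_fit_p, ss_total_p, _ = _fit_stats(y[perm], x)
        if f_stat(ss_fit_p, ss_total_p) >= f_obs:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_perm)
    return float(f_obs), float(p)


def anova_partial_rda(
    y, x, z, n_perm: int = 999, seed: Optional[int] = None
) -> tuple[float, float]:
    """Significance of X's contribution after the covariable block Z.

    Sequential decomposition: SS(X|Z) = SS_fit([Z X]) - SS_fit(Z);
    F = (SS(X|Z)/df_X) / (SS_res/(n - p_full - 1)) with response-row
    permutation.
    """
    y = _as_matrix(y)
    x = _as_matrix(x)
    z = _as_matrix(z)
    n = y.shape[0]
    full = np.hstack([z, x])

    def partial_f(y_mat: np.ndarray) -> float:
        ss_z, _, rank_z = _fit_stats(y_mat, z)
        ss_full, ss_total, rank_full = _fit_stats(y_mat, full)
        df_x = rank_full - rank_z
        df_res = n - rank_full - 1
        if df_x <= 0 or df_res <= 0:
            raise ValueError("partial design has no testable degrees of freedom")
        return ((ss_full - ss_z) / df_x) / ((ss_total - ss_full) / df_res)

    f_obs = partial_f(y)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if partial_f(y[perm]) >= f_obs:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_perm)
    return float(f_obs), float(p)


def forward_select(
    y,
    candidates: ExplanatorySet,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: Optional[int] = None,
) -> list[str]:
    """Greedy forward selection of explanatory variables.

    The global model with every candidate is tested first; selection
    only proceeds if it is significant at ``alpha`` (otherwise picking
    the best of k candidates would inflate the type-I error roughly
    k-fold).  Then, at each step, the candidate with the largest R^2
    gain is tested by permutation (partial F given the already-selected
    variables); the procedure stops when that p-value exceeds ``alpha``
    or when the cumulative adjusted R^2 would exceed the adjusted R^2
    of the global model (double stopping criterion).  May select
    nothing.
    """
    y = _as_matrix(y)
    frame = candidates.matrix
    n = y.shape[0]
    _, adj_global = rda_r2(y, frame)
    rng = np.random.default_rng(seed)
    _, p_global = anova_rda(y, frame, n_perm=n_perm, seed=int(rng.integers(2**31)))
    if p_global > alpha:
        return []

    selected: list[str] = []
    remaining = list(frame.columns)
    while remaining:
        x_sel = frame[selected].to_numpy(dtype=float) if selected else np.empty((n, 0))
        gains = []
        for col in remaining:
            x_new = np.hstack([x_sel, frame[[col]].to_numpy(dtype=float)])
            ss_fit, ss_total, _ = _fit_stats(y, x_new)
            gains.append(ss_fit / ss_total)
        best_idx = int(np.argmax(gains))
        best = remaining[best_idx]
        x_new = np.hstack([x_sel, frame[[best]].to_numpy(dtype=float)])

        if x_sel.shape[1]:
            f_obs, p = anova_partial_rda(
                y, frame[[best]].to_numpy(dtype=float), x_sel,
                n_perm=n_perm, seed=int(rng.integers(2**31)),
            )
        else:
            f_obs, p = anova_rda(
                y, frame[[best]].to_numpy(dtype=float),
                n_perm=n_perm, seed=int(rng.integers(2**31)),
            )
        if p > alpha:
            break
        _, adj_new = rda_r2(y, x_new)
        # adjusted-R^2 ceiling (second stopping criterion); not applied to
        # the first admission — with many noise candidates the global
        # model's adjustment penalty can fall below a single strong
        # variable's, and the permutation test already guards that step
        if selected and adj_new > adj_global:
            break
        selected.append(best)
        remaining.remove(best)
    return selected


@dataclass
class VarPartResult:
    """Inclusion-exclusion decomposition of adjusted R^2.

    ``fractions`` maps Venn-style labels to adjusted-R^2 fractions:
    single letters (``a``, ``b``, ...) are the unique fractions of each
    set in order, multi-letter labels the fractions shared by exactly
    those sets, and ``residual`` completes the total.  ``p_values``
    holds permutation p-values for the testable (unique and marginal)
    fractions.
    """

    set_names: list[str]
    fractions: dict[str, float]
    residual: float
    p_values: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"fraction": label, "adj_r2": value, "p": self.p_values.get(label, np.nan)}
            for label, value in self.fractions.items()
        ]
        rows.append({"fraction": "residual", "adj_r2": self.residual, "p": np.nan})
        return pd.DataFrame(rows)


def varpart(
    y,
    sets: Sequence[ExplanatorySet],
    n_perm: int = 999,
    seed: Optional[int] = None,
) -> VarPartResult:
    """Partition response variance over 2-4 explanatory sets.

    Adjusted R^2 is computed for every non-empty union of sets;
    inclusion-exclusion turns these into unique and shared fractions.
    Unique fractions are tested by partial RDA (conditioning on the
    union of the other sets); shared fractions are not testable and get
    no p-value.
    """
    if not 2 <= len(sets) <= 4:
        raise ValueError("varpart supports between 2 and 4 explanatory sets")
    y = _as_matrix(y)
    names = [s.name for s in sets]
    if len(set(names)) != len(names):
        raise ValueError("explanatory set names must be unique")
    k = len(sets)
    indices = tuple(range(k))

    def union_matrix(subset: tuple[int, ...]) -> np.ndarray:
        return np.hstack([_as_matrix(sets[i]) for i in subset])

    adj: dict[frozenset, float] = {frozenset(): 0.0}
    for r in range(1, k + 1):
        for subset in combinations(indices, r):
            _, a = rda_r2(y, union_matrix(subset))
            adj[frozenset(subset)] = a

    full = frozenset(indices)

    def h(w: frozenset) -> float:
        # variance NOT explained by the complement of w = cells inside w
        if not w:
            return 0.0
        return adj[full] - adj[full - w]

    def label(subset: frozenset) -> str:
        return "".join(_LETTERS[i] for i in sorted(subset))

    fractions: dict[str, float] = {}
    for r in range(1, k + 1):
        for subset in combinations(indices, r):
            s = frozenset(subset)
            value = 0.0
            for r2 in range(0, len(s) + 1):
                for w in combinations(sorted(s), r2):
                    value += (-1) ** (len(s) - len(w)) * h(frozenset(w))
            fractions[label(s)] = value

    rng = np.random.default_rng(seed)
    p_values: dict[str, float] = {}
    for i in indices:
        others = [j for j in indices if j != i]
        try:
            _, p = anova_partial_rda(
                y,
                _as_matrix(sets[i]),
                union_matrix(tuple(others)),
                n_perm=n_perm,
                seed=int(rng.integers(2**31)),
            )
        except ValueError:
            # set adds no rank beyond the others: fraction untestable
            p = float("nan")
        p_values[label(frozenset({i}))] = p

    residual = 1.0 - adj[full]
    return VarPartResult(
        set_names=names, fractions=fractions, residual=residual, p_values=p_values
    )
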