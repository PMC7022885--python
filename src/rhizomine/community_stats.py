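"""Multivariate community statistics.

Bray-Curtis dissimilarities over feature profiles feed three analyses:

* a two-factor PERMANOVA with interaction (McArdle-Anderson direct
  partitioning of the Gower-centered distance matrix, sequential
  Type-I sums of squares, free permutation of sample labels);
* non-metric multidimensional scaling (Kruskal stress-1, best of
  several random starts);
* one-tailed hypergeometric over-representation of pathways among a
  selected set of orthology identifiers.

The PERMANOVA table carries the conventional columns (Df, SS, MS,
pseudo-F, R^2, p, explained variance %); R^2 of a term is its share of
the total sum of squares, so the explained-% column is just 100*R^2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import hypergeom
from sklearn.manifold import smacof
from statsmodels.stats.multitest import multipletests

TERM_SEP = ":"
RESIDUAL = "Residual"
TOTAL = "Total"

PERMANOVA_COLUMNS = ["Df", "SS", "MS", "pseudo_F", "R2", "p", "explained_pct"]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with sample ids."""

    ids: list[str]
    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.ids)
        if self.data.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.data, self.data.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.data), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        if (self.data < -1e-12).any():
            raise ValueError("distances must be non-negative")

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.ids, columns=self.ids)

    def reorder(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix(list(ids), self.data[np.ix_(idx, idx)])


def bray_curtis(values: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples (columns).

    ``d_jk = sum_i |x_ij - x_ik| / sum_i (x_ij + x_ik)``; requires
    non-negative values and no all-zero sample (the dissimilarity is
    undefined there).
    """
    matrix = values.to_numpy(dtype=float).T  # samples x features
    if (matrix < 0).any():
        raise ValueError("Bray-Curtis requires non-negative values")
    if (matrix.sum(axis=1) == 0).any():
        zeros = [s for s, tot in zip(values.columns, matrix.sum(axis=1)) if tot == 0]
        raise ValueError(f"all-zero samples have no Bray-Curtis distance: {zeros}")
    dist = squareform(pdist(matrix, metric="braycurtis"))
    return DistanceMatrix(list(values.columns), dist)


# -- PERMANOVA -----------------------------------------------------------


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _dummy(meta: pd.DataFrame, factor: str) -> np.ndarray:
    levels = pd.unique(meta[factor])
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} has fewer than 2 levels")
    # full dummy coding; rank handled via projectors, so redundancy is fine
    return (meta[factor].to_numpy()[:, None] == levels[None, :]).astype(float)


def _term_matrix(meta: pd.DataFrame, term: str) -> np.ndarray:
    parts = term.split(TERM_SEP)
    blocks = [_dummy(meta, p) for p in parts]
    out = blocks[0]
    for block in blocks[1:]:
        out = np.einsum("ij,ik->ijk", out, block).reshape(out.shape[0], -1)
    return out


def _hat(x: np.ndarray) -> np.ndarray:
    # projection onto the column space; pinv handles redundant dummies
    return x @ np.linalg.pinv(x)


def permanova(
    d: DistanceMatrix,
    meta: pd.DataFrame,
    terms: Sequence[str] = ("genotype", "soil", "genotype:soil"),
    n_perm: int = 999,
    seed: Optional[int] = None,
    permutations: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Permutational multivariate ANOVA on a distance matrix.

    Sums of squares are partitioned directly from the Gower-centered
    matrix of squared distances; terms are entered sequentially in the
    given order (Type-I), with interactions written ``A:B``.  Each
    term's pseudo-F is its MS over the residual MS, and its p-value is
    ``(1 + #{permuted F >= observed}) / (1 + n_perm)`` under free
    permutation of sample labels (no strata).

    ``permutations`` may supply an explicit (n_perm x n) index array —
    e.g. the complete permutation group for small n — in which case the
    p-value is the exact fraction ``#{F >= observed} / n_perm`` over
    that set (no +1 correction, since the identity is a member).

    Returns the per-term table including Residual and Total rows.
    """
    missing = set(d.ids) - set(meta.index)
    if missing:
        raise ValueError(f"samples without metadata: {sorted(missing)}")
    meta = meta.loc[d.ids]
    n = d.n
    g = _gower_center(d.data)
    ss_total = float(np.trace(g))

    ones = np.ones((n, 1))
    designs = [ones]
    for term in terms:
        designs.append(np.hstack([designs[-1], _term_matrix(meta, term)]))
    hats = [_hat(x) for x in designs]
    ranks = [int(np.linalg.matrix_rank(x)) for x in designs]
    df_terms = [ranks[i + 1] - ranks[i] for i in range(len(terms))]
    df_resid = (n - 1) - sum(df_terms)
    if df_resid < 1:
        raise ValueError("model leaves no residual degrees of freedom")

    # difference projectors: SS_k = trace(M_k G), residual via I - H_full
    diffs = [hats[i + 1] - hats[i] for i in range(len(terms))]
    resid_proj = np.eye(n) - hats[-1]

    def seq_ss(g_mat: np.ndarray) -> tuple[np.ndarray, float]:
        ss = np.array([float(np.sum(m * g_mat)) for m in diffs])
        return ss, float(np.sum(resid_proj * g_mat))

    ss_terms, ss_resid = seq_ss(g)
    ms_terms = ss_terms / np.array(df_terms, dtype=float)
    ms_resid = ss_resid / df_resid
    f_obs = ms_terms / ms_resid

    p_values = np.full(len(terms), np.nan)
    if permutations is not None:
        perms = np.asarray(permutations)
    elif n_perm > 0:
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    else:
        perms = None
    if perms is not None:
        g_perms = g[perms[:, :, None], perms[:, None, :]]
        ss_p = np.stack(
            [np.einsum("ij,kij->k", m, g_perms) for m in diffs], axis=1
        )
        ss_resid_p = np.einsum("ij,kij->k", resid_proj, g_perms)
        f_perm = (ss_p / np.array(df_terms)) / (ss_resid_p / df_resid)[:, None]
        # tolerance absorbs round-off between permuted and observed paths
        tol = 1e-8 * np.maximum(1.0, np.abs(f_obs))
        exceed = (f_perm >= (f_obs - tol)[None, :]).sum(axis=0)
        if permutations is not None:
            p_values = exceed / len(perms)
        else:
            p_values = (1.0 + exceed) / (1.0 + n_perm)

    df_map = dict(zip(terms, df_terms))
    df_map[RESIDUAL] = df_resid
    ss_map = dict(zip(terms, ss_terms))
    ss_map[RESIDUAL] = ss_resid
    table = finalize_permanova_table(df_map, ss_map, ss_total)
    for term, p in zip(terms, p_values):
        table.loc[term, "p"] = p
    return table


def finalize_permanova_table(
    df_per_term: Mapping[str, int],
    ss_per_term: Mapping[str, float],
    ss_total: float,
) -> pd.DataFrame:
    """Derive MS, pseudo-F, R^2 and explained-% from Df and SS columns.

    ``ss_per_term`` must include the ``Residual`` entry; the returned
    table appends a ``Total`` row carrying only SS and R^2 = 1.
    """
    if RESIDUAL not in ss_per_term or RESIDUAL not in df_per_term:
        raise ValueError("a Residual entry is required")
    for term, df_t in df_per_term.items():
        if df_t <= 0:
            raise ValueError(f"non-positive Df for {term!r}")
    for term, ss in ss_per_term.items():
        if ss < 0:
            raise ValueError(f"negative SS for {term!r}")
        if ss > ss_total * (1 + 1e-9):
            raise ValueError(f"SS of {term!r} exceeds the total")

    ms_resid = ss_per_term[RESIDUAL] / df_per_term[RESIDUAL]
    rows = {}
    df_total = 0
    for term in df_per_term:
        df_t = df_per_term[term]
        ss = ss_per_term[term]
        ms = ss / df_t
        r2 = ss / ss_total
        rows[term] = {
            "Df": df_t,
            "SS": ss,
            "MS": ms,
            "pseudo_F": np.nan if term == RESIDUAL else ms / ms_resid,
            "R2": r2,
            "p": np.nan,
            "explained_pct": 100.0 * r2,
        }
        df_total += df_t
    rows[TOTAL] = {
        "Df": df_total,
        "SS": ss_total,
        "MS": np.nan,
        "pseudo_F": np.nan,
        "R2": 1.0,
        "p": np.nan,
        "explained_pct": 100.0,
    }
    return pd.DataFrame.from_dict(rows, orient="index")[PERMANOVA_COLUMNS]


# -- NMDS ----------------------------------------------------------------


@dataclass
class NmdsResult:
    """Ordination coordinates and the Kruskal stress-1 achieved."""

    coordinates: pd.DataFrame
    stress: float


def _classical_scaling(d: np.ndarray, k: int) -> np.ndarray:
    """Principal-coordinate (Torgerson) configuration in k dimensions."""
    g = _gower_center(d)
    eigvals, eigvecs = np.linalg.eigh(g)
    order = np.argsort(eigvals)[::-1][:k]
    coords = eigvecs[:, order] * np.sqrt(np.clip(eigvals[order], 0.0, None))
    return coords


def nmds(
    d: DistanceMatrix,
    k: int = 2,
    n_starts: int = 16,
    seed: Optional[int] = None,
    max_iter: int = 300,
) -> NmdsResult:
    """Non-metric MDS minimizing Kruskal stress-1.

    Runs SMACOF with monotone regression from a classical-scaling
    (principal coordinates) start plus ``n_starts - 1`` random starts,
    keeping the lowest-stress solution.  The deterministic start makes
    the result invariant to sample relabeling.
    """
    if k >= d.n - 1:
        raise ValueError(f"k={k} requires more than {k + 1} samples")
    coords, stress = smacof(
        d.data,
        metric=False,
        n_components=k,
        init=_classical_scaling(d.data, k),
        n_init=1,
        max_iter=max_iter,
        normalized_stress=True,
    )
    if n_starts > 1:
        coords_r, stress_r = smacof(
            d.data,
            metric=False,
            n_components=k,
            n_init=n_starts - 1,
            max_iter=max_iter,
            random_state=seed,
            normalized_stress=True,
        )
        if stress_r < stress:
            coords, stress = coords_r, stress_r
    frame = pd.DataFrame(
        coords, index=d.ids, columns=[f"NMDS{i + 1}" for i in range(k)]
    )
    return NmdsResult(coordinates=frame, stress=float(stress))


# -- pathway over-representation -----------------------------------------


def hypergeom_enrichment(
    selected: Iterable[str],
    universe: Iterable[str],
    pathway_map: Mapping[str, Iterable[str]],
    p_cut: float = 0.1,
) -> pd.DataFrame:
    """One-tailed hypergeometric over-representation of pathways.

    ``selected`` must be a subset of ``universe``.  For each pathway
    with members in the universe, the upper-tail probability of drawing
    at least the observed overlap when sampling ``|selected|`` ids
    without replacement is computed; BH adjustment is applied across
    pathways and rows with raw ``p < p_cut`` are flagged enriched.
    """
    selected = set(selected)
    universe = set(universe)
    if not selected <= universe:
        raise ValueError("selected ids must be a subset of the universe")
    empty_cols = [
        "pathway",
        "overlap",
        "pathway_size",
        "selected_size",
        "universe_size",
        "p",
        "fdr",
        "enriched",
    ]
    if not selected:
        return pd.DataFrame(columns=empty_cols)
    rows = []
    n_univ = len(universe)
    n_sel = len(selected)
    for pathway, members in sorted(pathway_map.items()):
        members = set(members) & universe
        if not members:
            continue
        overlap = len(members & selected)
        p = float(hypergeom.sf(overlap - 1, n_univ, len(members), n_sel))
        rows.append(
            {
                "pathway": pathway,
                "overlap": overlap,
                "pathway_size": len(members),
                "selected_size": n_sel,
                "universe_size": n_univ,
                "p": min(max(p, 0.0), 1.0),
            }
        )
    if not rows:
        return pd.DataFrame(columns=empty_cols)
    frame = pd.DataFrame(rows)
    _, fdr, _, _ = multipletests(frame["p"], method="fdr_bh")
    frame["fdr"] = fdr
    frame["enriched"] = frame["p"] < p_cut
    return frame.sort_values("p", kind="mergesort").reset_index(drop=True)
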