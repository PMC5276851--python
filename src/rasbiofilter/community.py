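"""Community-composition statistics on sample x taxon tables.

Implements the distance-based toolkit used for amplicon community
comparison: Bray-Curtis dissimilarity, complete-linkage agglomerative
clustering, principal-coordinates analysis (classical MDS via Gower
double-centering), environmental vector fitting onto the first two
ordination axes with permutation significance, one-factor PERMANOVA with
free label permutation, within-group percent-similarity summaries, and
the minimum-substantive-abundance rule used when partitioning amplicon
reads into nodes.

All statistics are computed directly from their definitions on dense
numpy arrays; the fixtures here are tens of samples, not thousands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CommunityTable",
    "DistanceMatrix",
    "EnvFitResult",
    "PermanovaResult",
    "Ordination",
    "relative_abundance",
    "bray_curtis",
    "complete_linkage",
    "dendrogram_to_newick",
    "pcoa",
    "envfit",
    "envfit_table",
    "permanova",
    "within_group_similarity",
    "med_minimum_abundance",
]


@dataclass
class CommunityTable:
    """Sample x taxon abundance table with optional group labels.

    ``data`` holds nonnegative counts or proportions (samples as rows);
    ``groups`` maps each sample to a categorical factor such as depth or
    sand/water habitat.
    """

    data: pd.DataFrame
    groups: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.data.to_numpy() < 0).any():
            raise ValueError("community table contains negative entries")
        if self.groups is not None:
            self.groups = self.groups.reindex(self.data.index)
            if self.groups.isna().any():
                raise ValueError("group labels missing for some samples")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class DistanceMatrix:
    """Square symmetric dissimilarity matrix with zero diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass(frozen=True)
class EnvFitResult:
    variable: str
    dim1: float
    dim2: float
    r_squared: float
    p: float
    degenerate: bool = False


@dataclass(frozen=True)
class PermanovaResult:
    F: float
    r_squared: float
    p: float
    n_perm: int


@dataclass
class Ordination:
    """PCoA result: sample scores, eigenvalues, percent variance per axis."""

    ids: list[str]
    coordinates: np.ndarray  # samples x axes, axes ordered by eigenvalue
    eigenvalues: np.ndarray  # all eigenvalues, descending (may be negative)
    percent_variance: np.ndarray  # per retained (positive) axis

    def to_frame(self) -> pd.DataFrame:
        cols = [f"axis{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.ids, columns=cols)


def relative_abundance(table: CommunityTable) -> CommunityTable:
    """Convert counts to row-wise proportions (each sample sums to 1)."""
    sums = table.data.sum(axis=1)
    if (sums <= 0).any():
        empty = list(sums.index[sums <= 0])
        raise ValueError(f"cannot normalise samples with zero total: {empty}")
    return CommunityTable(table.data.div(sums, axis=0), table.groups)


def bray_curtis(table: CommunityTable, *, normalize: bool = True) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity: sum|x-y| / sum(x+y).

    Rows are converted to relative abundances first (the amplicon
    convention); pass ``normalize=False`` to compare raw counts. A pair of
    all-zero samples is assigned distance 0 with a warning.
    """
    if len(table.data) < 2:
        raise ValueError("Bray-Curtis needs >=2 samples")
    if normalize and (table.data.sum(axis=1) > 0).all():
        table = relative_abundance(table)
    x = table.data.to_numpy(dtype=float)
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        num = np.abs(x[i] - x[i + 1 :]).sum(axis=1)
        den = (x[i] + x[i + 1 :]).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            row = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        if np.any(den == 0):
            warnings.warn(
                "pair(s) of all-zero samples assigned Bray-Curtis distance 0",
                stacklevel=2,
            )
        d[i, i + 1 :] = row
        d[i + 1 :, i] = row
    return DistanceMatrix(table.sample_ids, d)


def complete_linkage(D: DistanceMatrix) -> list[tuple[int, int, float]]:
    """Agglomerative clustering with the maximum (complete) linkage rule.

    Returns scipy-style merges ``(a, b, height)`` where leaves are
    0..n-1 and the merge at step k creates cluster ``n + k``. Ties are
    broken by the smallest (row, column) index pair, so dendrograms are
    deterministic. Direct O(n^3) implementation of the definition.
    """
    n = len(D.ids)
    if n < 2:
        raise ValueError("clustering needs >=2 samples")
    dist = {
        (i, j): float(D.values[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    active: dict[int, None] = {i: None for i in range(n)}
    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(active) > 1:
        ids = sorted(active)
        best = None
        for ai, a in enumerate(ids):
            for b in ids[ai + 1 :]:
                d = dist[(min(a, b), max(a, b))]
                if best is None or d < best[0] - 1e-15:
                    best = (d, a, b)
        d, a, b = best
        merges.append((a, b, d))
        # Complete linkage: distance to the union is the max of the parts.
        del active[a], active[b]
        for c in active:
            da = dist.pop((min(a, c), max(a, c)))
            db = dist.pop((min(b, c), max(b, c)))
            dist[(min(next_id, c), max(next_id, c))] = max(da, db)
        active[next_id] = None
        next_id += 1
    return merges


def dendrogram_to_newick(
    merges: Sequence[tuple[int, int, float]], ids: Sequence[str]
) -> str:
    """Render a merge list as a Newick string with branch lengths.

    Branch length of a node is the difference between its parent's merge
    height and its own (leaves sit at height 0).
    """
    n = len(ids)
    label: dict[int, str] = {i: str(ids[i]) for i in range(n)}
    height: dict[int, float] = {i: 0.0 for i in range(n)}
    node = n
    for a, b, h in merges:
        la = f"{label[a]}:{h - height[a]:.6g}"
        lb = f"{label[b]}:{h - height[b]:.6g}"
        label[node] = f"({la},{lb})"
        height[node] = h
        node += 1
    return label[node - 1] + ";"


def pcoa(D: DistanceMatrix) -> Ordination:
    """Principal-coordinates analysis (classical metric MDS).

    Gower double-centering of -D^2/2 followed by eigendecomposition.
    Axes are ordered by eigenvalue; coordinates are kept for positive
    eigenvalues only, and percent variance is each positive eigenvalue
    over the positive-eigenvalue total (negative eigenvalues from a
    non-Euclidean dissimilarity are dropped, no correction applied).
    """
    n = len(D.ids)
    if n < 3:
        raise ValueError("PCoA needs >=3 samples")
    a = -0.5 * D.values**2
    centering = np.eye(n) - np.ones((n, n)) / n
    g = centering @ a @ centering
    eigvals, eigvecs = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    tol = max(1e-10, 1e-10 * abs(eigvals[0]) if eigvals.size else 0.0)
    pos = eigvals > tol
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    pct = 100.0 * eigvals[pos] / eigvals[pos].sum()
    return Ordination(
        ids=list(D.ids),
        coordinates=coords,
        eigenvalues=eigvals,
        percent_variance=pct,
    )


def _envfit_r2(scores: np.ndarray, env: np.ndarray) -> tuple[np.ndarray, float]:
    """OLS of env on two axis scores; returns (coefficients, R^2)."""
    X = np.column_stack([np.ones(len(env)), scores])
    beta, *_ = np.linalg.lstsq(X, env, rcond=None)
    fitted = X @ beta
    ss_res = float(np.sum((env - fitted) ** 2))
    ss_tot = float(np.sum((env - env.mean()) ** 2))
    r2 = 0.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return beta[1:], r2


def envfit(
    ordination: Ordination,
    env: Sequence[float],
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
    *,
    variable: str = "env",
) -> EnvFitResult:
    """Fit one environmental vector onto the first two ordination axes.

    The variable is regressed on the axis-1/axis-2 scores; the reported
    direction cosines are the normalised regression coefficients and R^2
    is the squared multiple correlation. Significance comes from
    permuting the variable's values across samples:
    ``p = (b + 1)/(n_perm + 1)`` with b the count of permuted R^2 >=
    observed. A constant variable yields a zero vector, R^2 = 0, p = 1,
    flagged degenerate.
    """
    e = np.asarray(env, dtype=float)
    if e.size != len(ordination.ids):
        raise ValueError("env must have one value per ordinated sample")
    if e.size < 3:
        raise ValueError("envfit needs >=3 samples")
    scores = ordination.coordinates[:, :2]
    if scores.shape[1] < 2:
        scores = np.column_stack([scores, np.zeros(len(e))])
    if np.ptp(e) == 0:
        return EnvFitResult(variable, 0.0, 0.0, 0.0, 1.0, degenerate=True)
    coef, r2 = _envfit_r2(scores, e)
    norm = float(np.hypot(*coef))
    dim1, dim2 = (coef / norm) if norm > 0 else (0.0, 0.0)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    b = 0
    for _ in range(n_perm):
        _, r2_perm = _envfit_r2(scores, rng.permutation(e))
        if r2_perm >= r2 - 1e-12:
            b += 1
    return EnvFitResult(
        variable=variable,
        dim1=float(dim1),
        dim2=float(dim2),
        r_squared=r2,
        p=(b + 1) / (n_perm + 1),
    )


def envfit_table(
    ordination: Ordination,
    env_table: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Run :func:`envfit` on every column of ``env_table``.

    Returns the familiar four-column layout (Dim1, Dim2, R2, p) indexed
    by variable name.
    """
    rng = np.random.default_rng(seed)
    env_table = env_table.loc[ordination.ids]
    rows = []
    for name in env_table.columns:
        res = envfit(ordination, env_table[name].to_numpy(), n_perm, rng, variable=name)
        rows.append(
            {
                "variable": name,
                "Dim1": res.dim1,
                "Dim2": res.dim2,
                "R2": res.r_squared,
                "p": res.p,
            }
        )
    return pd.DataFrame(rows).set_index("variable")


def _permanova_stats(
    d2: np.ndarray, labels: np.ndarray
) -> tuple[float, float]:
    """Pseudo-F and R^2 from squared distances and group labels."""
    n = len(labels)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    k = 0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        k += 1
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    ss_between = ss_total - ss_within
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    if n - k <= 0 or ss_within == 0:
        f = np.inf if ss_between > 0 else 0.0
    else:
        f = (ss_between / (k - 1)) / (ss_within / (n - k))
    return f, r2


def permanova(
    D: DistanceMatrix,
    groups: Sequence[str] | pd.Series,
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """One-factor PERMANOVA on a distance matrix.

    Partitions the total sum of squared dissimilarities
    (``SS_total = sum_{i<j} d_ij^2 / n``) into within- and between-group
    components; the pseudo-F statistic is tested by freely permuting the
    group labels (no strata), ``p = (b + 1)/(n_perm + 1)``.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if isinstance(groups, pd.Series):
        missing = [i for i in D.ids if i not in groups.index]
        if missing:
            raise ValueError(f"group labels missing for samples: {missing}")
        labels = groups.loc[list(D.ids)].to_numpy()
    else:
        labels = np.asarray(list(groups))
        if labels.size != len(D.ids):
            raise ValueError("need one group label per sample")
    if len(np.unique(labels)) < 2:
        raise ValueError("PERMANOVA needs >=2 groups")
    d2 = D.values**2
    f_obs, r2 = _permanova_stats(d2, labels)
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_perm):
        f_perm, _ = _permanova_stats(d2, rng.permutation(labels))
        if f_perm >= f_obs - 1e-12:
            b += 1
    return PermanovaResult(
        F=float(f_obs), r_squared=float(r2), p=(b + 1) / (n_perm + 1), n_perm=n_perm
    )


def within_group_similarity(
    D: DistanceMatrix, groups: Sequence[str] | pd.Series
) -> pd.DataFrame:
    """Mean +/- SD percent similarity (100*(1-d)) over within-group pairs.

    Groups with fewer than two samples are excluded with a warning.
    Returns a table indexed by group with mean, sd and pair count.
    """
    if isinstance(groups, pd.Series):
        labels = groups.loc[list(D.ids)].to_numpy()
    else:
        labels = np.asarray(list(groups))
    rows = []
    for g in pd.unique(labels):
        idx = np.flatnonzero(labels == g)
        if idx.size < 2:
            warnings.warn(f"group {g!r} has <2 samples; excluded", stacklevel=2)
            continue
        sub = D.values[np.ix_(idx, idx)]
        sims = 100.0 * (1.0 - sub[np.triu_indices(idx.size, 1)])
        rows.append(
            {
                "group": g,
                "mean_similarity": float(sims.mean()),
                "sd_similarity": float(sims.std(ddof=1)) if sims.size > 1 else 0.0,
                "n_pairs": int(sims.size),
            }
        )
    return pd.DataFrame(rows).set_index("group")


def med_minimum_abundance(total_reads: int) -> int:
    """Minimum-substantive-abundance threshold for amplicon node inclusion.

    ``floor(total_reads / 50000)`` with a floor of 1, following the
    best-practice rule of scaling the node-inclusion threshold to dataset
    size.
    """
    if total_reads < 1:
        raise ValueError("total_reads must be >= 1")
    return max(1, int(total_reads) // 50_000)
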