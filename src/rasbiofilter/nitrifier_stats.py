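"""Abundance-pattern statistics for nitrifier marker-gene time series.

Covers the univariate toolkit applied to qPCR copy-number series:
coefficients of variation, pairwise Pearson correlations with permutation
("pseudo") p-values, Kruskal-Wallis tests of depth stratification, and
numerator/denominator dominance ratios between genotype groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationResult",
    "KruskalWallisResult",
    "DepthSummary",
    "DEPTH_LABELS",
    "coefficient_of_variation",
    "pearson_r",
    "permutation_pseudo_p",
    "correlation_matrix",
    "kruskal_wallis",
    "depth_summary",
    "dominance_ratio",
]

DEPTH_LABELS = ("surface", "middle", "bottom")


@dataclass(frozen=True)
class CorrelationResult:
    pair: tuple[str, str]
    r: float
    pseudo_p: float
    n_permutations: int
    n_obs: int


@dataclass(frozen=True)
class KruskalWallisResult:
    """Kruskal-Wallis rank-sum statistic, reported on the chi-squared scale."""

    H: float
    df: int
    p: float


@dataclass
class DepthSummary:
    """Per assay x depth mean/SD/n with an attached depth test per assay."""

    table: pd.DataFrame  # columns: assay, depth, mean, sd, n, sd_degenerate
    tests: dict[str, KruskalWallisResult]


def coefficient_of_variation(series: Sequence[float]) -> float:
    """Sample SD (n-1) over mean; scale-invariant dispersion measure."""
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("CV needs >=2 values")
    m = x.mean()
    if m == 0:
        raise ValueError("CV undefined for zero-mean series")
    return float(x.std(ddof=1) / m)


def _check_pair(x: np.ndarray, y: np.ndarray) -> None:
    if x.size != y.size:
        raise ValueError("series must have equal length")
    if x.size < 3:
        raise ValueError("correlation needs >=3 observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for zero-variance series")


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation coefficient."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    _check_pair(xa, ya)
    return float(np.corrcoef(xa, ya)[0, 1])


def permutation_pseudo_p(
    x: Sequence[float],
    y: Sequence[float],
    n_perm: int = 4999,
    seed: int | np.random.Generator = 0,
    *,
    pair: tuple[str, str] = ("x", "y"),
) -> CorrelationResult:
    """Two-sided permutation p-value for a Pearson correlation.

    One series is shuffled ``n_perm`` times while the other stays fixed;
    the pseudo-p is ``(b + 1) / (n_perm + 1)`` where ``b`` counts
    permutations with ``|r_perm| >= |r_obs|``. The add-one correction
    bounds the p-value below by ``1/(n_perm+1)`` — 0.0002 at the default
    4999 permutations.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    _check_pair(xa, ya)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    r_obs = float(np.corrcoef(xa, ya)[0, 1])
    # Centred/normalised x lets each permuted r be a single dot product.
    xc = (xa - xa.mean()) / (xa.std() * xa.size)
    yc = (ya - ya.mean()) / ya.std()
    b = 0
    for _ in range(n_perm):
        r_perm = float(xc @ rng.permutation(yc))
        if abs(r_perm) >= abs(r_obs) - 1e-12:
            b += 1
    return CorrelationResult(
        pair=pair,
        r=r_obs,
        pseudo_p=(b + 1) / (n_perm + 1),
        n_permutations=n_perm,
        n_obs=int(xa.size),
    )


def correlation_matrix(
    markers: pd.DataFrame,
    n_perm: int = 4999,
    seed: int = 0,
    *,
    log_scale: bool = False,
) -> pd.DataFrame:
    """All pairwise assay correlations over the shared time series.

    Series are aligned on ``sample_id``; correlations are computed on raw
    copy numbers by default (``log_scale=True`` switches to log10).
    Returns a long table (assay_a, assay_b, r, pseudo_p, n_obs).
    """
    wide = markers.pivot_table(
        index="sample_id", columns="assay", values="cn_per_g"
    ).dropna()
    if log_scale:
        wide = np.log10(wide)
    rng = np.random.default_rng(seed)
    rows = []
    for a, b in combinations(sorted(wide.columns), 2):
        res = permutation_pseudo_p(
            wide[a].to_numpy(), wide[b].to_numpy(), n_perm, rng, pair=(a, b)
        )
        rows.append(
            {
                "assay_a": a,
                "assay_b": b,
                "r": res.r,
                "pseudo_p": res.pseudo_p,
                "n_obs": res.n_obs,
            }
        )
    return pd.DataFrame(rows)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> KruskalWallisResult:
    """Kruskal-Wallis rank-sum test across >=2 groups.

    Tie-corrected H with a chi-squared (df = k-1) p-value. When every
    pooled observation is identical the statistic degenerates to H = 0,
    p = 1 rather than an error, so fully-tied fixtures still summarise.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need >=2 groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group needs >=1 observation")
    if sum(a.size for a in arrays) < 3:
        raise ValueError("need >=3 total observations")
    df = len(arrays) - 1
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return KruskalWallisResult(H=0.0, df=df, p=1.0)
    H, p = stats.kruskal(*arrays)
    return KruskalWallisResult(H=float(H), df=df, p=float(p))


def depth_summary(markers: pd.DataFrame) -> DepthSummary:
    """Mean +/- SD per assay x depth plus a Kruskal-Wallis depth test.

    Depth labels must come from ``DEPTH_LABELS``. A depth cell with a
    single sample reports SD = 0 and is flagged ``sd_degenerate`` so the
    summary table is always fully populated.
    """
    bad = set(markers["depth"].unique()) - set(DEPTH_LABELS)
    if bad:
        raise ValueError(
            f"unknown depth labels {sorted(bad)}; valid labels are {list(DEPTH_LABELS)}"
        )
    rows = []
    tests: dict[str, KruskalWallisResult] = {}
    for assay, sub in markers.groupby("assay", sort=False):
        series_by_depth = []
        for depth in DEPTH_LABELS:
            vals = sub.loc[sub["depth"] == depth, "cn_per_g"].to_numpy()
            if vals.size == 0:
                continue
            degenerate = vals.size == 1
            rows.append(
                {
                    "assay": assay,
                    "depth": depth,
                    "mean": float(vals.mean()),
                    "sd": 0.0 if degenerate else float(vals.std(ddof=1)),
                    "n": int(vals.size),
                    "sd_degenerate": degenerate,
                }
            )
            series_by_depth.append(vals)
        if len(series_by_depth) >= 2 and sum(v.size for v in series_by_depth) >= 3:
            tests[assay] = kruskal_wallis(series_by_depth)
    return DepthSummary(table=pd.DataFrame(rows), tests=tests)


def dominance_ratio(
    numerator_assays: Sequence[str],
    denominator_assays: Sequence[str],
    markers: pd.DataFrame,
) -> tuple[pd.Series, tuple[float, float]]:
    """Per-sample abundance ratio between two genotype groups.

    For each sample, sum(numerator CN/g) / sum(denominator CN/g).
    Samples with a zero denominator are excluded with a warning. Returns
    the per-sample ratios and their (min, max) range.
    """
    present = set(markers["assay"].unique())
    missing = [a for a in (*numerator_assays, *denominator_assays) if a not in present]
    if missing:
        raise ValueError(f"assays missing from marker table: {missing}")
    wide = markers.pivot_table(
        index="sample_id", columns="assay", values="cn_per_g", aggfunc="mean"
    )
    num = wide[list(numerator_assays)].sum(axis=1)
    den = wide[list(denominator_assays)].sum(axis=1)
    zero = den == 0
    if zero.any():
        warnings.warn(
            f"excluding {int(zero.sum())} sample(s) with zero denominator: "
            f"{list(wide.index[zero])}",
            stacklevel=2,
        )
    ratios = (num[~zero] / den[~zero]).rename("ratio")
    if ratios.empty:
        raise ValueError("no samples with nonzero denominator")
    return ratios, (float(ratios.min()), float(ratios.max()))
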