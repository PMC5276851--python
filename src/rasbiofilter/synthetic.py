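"""Seeded synthetic inputs with the statistical structure of RAS biofilter data.

Three generators emulate the tabular inputs the analysis consumes:

* water-chemistry time series — truncated-normal draws around configured
  means/SDs for influent/effluent nitrogen species and operational
  covariates, plus a deterministic fish-count trajectory;
* marker-gene copy-number series — log-normal marginals with configured
  means and CVs, cross-genotype correlation planted on the log scale via
  a Gaussian copula, multiplicative depth effects and a replicate-SD
  column mimicking qPCR triplicate scatter;
* community tables — Dirichlet-distributed sample x taxon proportions
  around group-shifted baseline compositions.

Default parameter values are set to the published UWM biofilter summary
statistics (chemistry means/SDs, genotype abundances and CVs, the
pairwise abundance correlations) so that the default synthetic system
behaves like the study system. One global seed expands to independent
per-stream child seeds, so adding a stream never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ChemistryConfig",
    "MarkerSimConfig",
    "CommunitySimConfig",
    "DEFAULT_GENOTYPES",
    "DEFAULT_CORRELATION",
    "generate_chemistry_series",
    "generate_marker_series",
    "generate_community_table",
]

# Fixed stream ids: child seeds are SeedSequence((seed, stream_id)).
_STREAM_CHEMISTRY = 11
_STREAM_MARKERS = 12
_STREAM_COMMUNITY = 13

DEPTHS = ("surface", "middle", "bottom")

DEFAULT_GENOTYPES = (
    "aoa_total",
    "nitroso_1",
    "nitroso_2",
    "nxrb_uwm_1",
    "nxrb_uwm_2",
    "comammox",
)

#: Log-scale abundance correlations between genotypes, assembled from the
#: reported pairwise time-series correlations (Nitrosomonas genotype pair
#: 0.90, nxrB genotype pair 0.71, AOA-nxrB-1 0.90, comammox-nxrB-2 0.82,
#: Nitrosomonas vs AOA/comammox 0.65/0.69); unreported pairs filled with
#: moderate values keeping the matrix positive definite.
DEFAULT_CORRELATION = pd.DataFrame(
    [
        # aoa   n1    n2    nx1   nx2   com
        [1.00, 0.65, 0.65, 0.90, 0.60, 0.60],
        [0.65, 1.00, 0.90, 0.55, 0.55, 0.69],
        [0.65, 0.90, 1.00, 0.55, 0.55, 0.69],
        [0.90, 0.55, 0.55, 1.00, 0.71, 0.60],
        [0.60, 0.55, 0.55, 0.71, 1.00, 0.82],
        [0.60, 0.69, 0.69, 0.60, 0.82, 1.00],
    ],
    index=DEFAULT_GENOTYPES,
    columns=DEFAULT_GENOTYPES,
)

#: Depth-category abundance multipliers (relative to the genotype's grand
#: mean), reflecting the strong bottom enrichment of the Nitrosomonas
#: genotypes and the comparative depth stability of AOA, comammox and the
#: nitrite-oxidizer genotypes.
DEFAULT_DEPTH_MULTIPLIERS = {
    "aoa_total": {"surface": 0.53, "middle": 1.37, "bottom": 1.11},
    "nitroso_1": {"surface": 0.25, "middle": 0.20, "bottom": 2.55},
    "nitroso_2": {"surface": 0.38, "middle": 0.44, "bottom": 2.18},
    "nxrb_uwm_1": {"surface": 0.78, "middle": 1.25, "bottom": 0.98},
    "nxrb_uwm_2": {"surface": 0.92, "middle": 1.01, "bottom": 1.07},
    "comammox": {"surface": 0.76, "middle": 1.18, "bottom": 1.06},
}


def _child_rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), stream)))


@dataclass
class ChemistryConfig:
    """Truncated-normal chemistry/operations generator settings.

    Each variable is (mean, SD); concentrations are in uM, covariates in
    their native units. The fish count follows a deterministic
    exponential-survival trajectory from ``initial_fish`` at the daily
    mortality rate.
    """

    n_days: int = 100
    sampling_interval_days: float = 1.0
    influent_ammonia: tuple[float, float] = (9.02, 4.76)
    effluent_ammonia: tuple[float, float] = (3.84, 7.32)
    influent_nitrite: tuple[float, float] = (1.69, 1.46)
    effluent_nitrite: tuple[float, float] = (0.73, 0.49)
    ph: tuple[float, float] = (7.01, 0.09)
    water_temp_c: tuple[float, float] = (21.7, 0.9)
    conductivity_us: tuple[float, float] = (600.0, 50.0)
    orp_mv: tuple[float, float] = (540.0, 50.0)
    feed_size_mm: tuple[float, float] = (3.0, 1.0)
    kg_feed: tuple[float, float] = (5.0, 2.0)
    initial_fish: int = 20_000
    daily_mortality: float = 0.001
    seed: int = 0

    _VARIABLES = (
        "influent_ammonia",
        "effluent_ammonia",
        "influent_nitrite",
        "effluent_nitrite",
        "ph",
        "water_temp_c",
        "conductivity_us",
        "orp_mv",
        "feed_size_mm",
        "kg_feed",
    )

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.sampling_interval_days <= 0:
            raise ValueError("sampling_interval_days must be > 0")
        for name in self._VARIABLES:
            _, sd = getattr(self, name)
            if sd < 0:
                raise ValueError(f"SD of {name} must be >= 0")
        if not 0 <= self.daily_mortality < 1:
            raise ValueError("daily_mortality must be in [0, 1)")


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, n: int
) -> np.ndarray:
    """Normal truncated at zero from below; degenerate at the mean if SD=0."""
    if sd == 0:
        return np.full(n, float(mean))
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)


def generate_chemistry_series(config: ChemistryConfig) -> pd.DataFrame:
    """One record per timepoint of chemistry and operations covariates."""
    rng = _child_rng(config.seed, _STREAM_CHEMISTRY)
    days = np.arange(config.n_days) * config.sampling_interval_days
    out = {"day": days}
    for name in config._VARIABLES:
        mean, sd = getattr(config, name)
        out[name] = _truncated_normal(rng, mean, sd, config.n_days)
    out["n_fish"] = np.round(
        config.initial_fish * (1.0 - config.daily_mortality) ** days
    ).astype(int)
    return pd.DataFrame(out)


@dataclass
class MarkerSimConfig:
    """Correlated log-normal marker-gene series settings.

    ``mean_cn`` and ``cv`` give each genotype's marginal mean copy number
    (CN per g wet sand) and coefficient of variation; ``correlation`` is
    the cross-genotype correlation of log abundances (symmetric, unit
    diagonal, positive semidefinite). ``depth_multipliers`` scale each
    genotype by depth category. The generated table carries
    ``n_timepoints`` surface time-series samples (one per
    ``sampling_interval_days``) plus ``n_depth_samples`` per depth
    category, with a replicate-SD column at ``replicate_noise_cv`` of the
    reported value.
    """

    genotypes: tuple[str, ...] = DEFAULT_GENOTYPES
    mean_cn: dict[str, float] = field(
        default_factory=lambda: {
            "aoa_total": 1.9e8,
            "nitroso_1": 1.8e5,
            "nitroso_2": 9.2e3,
            "nxrb_uwm_1": 5.9e8,
            "nxrb_uwm_2": 4.6e8,
            "comammox": 3.3e8,
        }
    )
    cv: dict[str, float] = field(
        default_factory=lambda: {
            "aoa_total": 0.38,
            "nitroso_1": 1.33,
            "nitroso_2": 1.32,
            "nxrb_uwm_1": 0.45,
            "nxrb_uwm_2": 0.45,
            "comammox": 0.55,
        }
    )
    correlation: pd.DataFrame | None = None
    depth_multipliers: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            g: dict(m) for g, m in DEFAULT_DEPTH_MULTIPLIERS.items()
        }
    )
    n_timepoints: int = 15
    sampling_interval_days: float = 7.0
    n_depth_samples: int = 4
    replicate_noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.correlation is None:
            self.correlation = DEFAULT_CORRELATION.loc[
                list(self.genotypes), list(self.genotypes)
            ]
        corr = self.correlation.loc[list(self.genotypes), list(self.genotypes)]
        r = corr.to_numpy(dtype=float)
        if not np.allclose(r, r.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(r), 1.0, atol=1e-10):
            raise ValueError("correlation matrix must have a unit diagonal")
        eigvals = np.linalg.eigvalsh(r)
        if eigvals.min() < -1e-10:
            raise ValueError(
                "correlation matrix is not positive semidefinite "
                f"(smallest eigenvalue {eigvals.min():.3e})"
            )
        self.correlation = corr
        for g in self.genotypes:
            if self.mean_cn[g] <= 0:
                raise ValueError(f"mean copy number of {g} must be > 0")
            if self.cv[g] < 0:
                raise ValueError(f"CV of {g} must be >= 0")
        if self.replicate_noise_cv < 0:
            raise ValueError("replicate_noise_cv must be >= 0")
        if self.n_timepoints < 0 or self.n_depth_samples < 0:
            raise ValueError("sample counts must be >= 0")
        if self.n_timepoints + self.n_depth_samples == 0:
            raise ValueError("at least one sample must be generated")


def _correlated_lognormal(
    rng: np.random.Generator, config: MarkerSimConfig, n: int
) -> np.ndarray:
    """n x genotype draws: lognormal marginals, planted log-scale correlation."""
    g = list(config.genotypes)
    r = config.correlation.to_numpy(dtype=float)
    # Eigen-based square root tolerates singular (CV=0 collapses later anyway).
    w, v = np.linalg.eigh(r)
    chol = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    z = rng.standard_normal((n, len(g))) @ chol.T
    sigma = np.array([np.sqrt(np.log1p(config.cv[k] ** 2)) for k in g])
    mu = np.array([np.log(config.mean_cn[k]) for k in g]) - sigma**2 / 2.0
    return np.exp(mu + sigma * z)


def generate_marker_series(config: MarkerSimConfig) -> pd.DataFrame:
    """Long marker table: assay, sample_id, day, depth, cn_per_g, sd."""
    rng = _child_rng(config.seed, _STREAM_MARKERS)
    samples: list[tuple[str, float, str]] = []  # (sample_id, day, depth)
    for i in range(config.n_timepoints):
        samples.append((f"T{i:02d}", i * config.sampling_interval_days, "surface"))
    profile_day = (
        (config.n_timepoints - 1) * config.sampling_interval_days
        if config.n_timepoints
        else 0.0
    )
    for depth in DEPTHS:
        for i in range(config.n_depth_samples):
            samples.append((f"D-{depth}-{i}", profile_day, depth))
    values = _correlated_lognormal(rng, config, len(samples))
    rows = []
    for row, (sample_id, day, depth) in zip(values, samples):
        is_profile = sample_id.startswith("D-")
        for val, genotype in zip(row, config.genotypes):
            # Depth effects are a property of the spatial profile; the
            # surface time series is left on the marginal scale so the
            # planted means/CVs are recovered from it directly.
            mult = (
                config.depth_multipliers.get(genotype, {}).get(depth, 1.0)
                if is_profile
                else 1.0
            )
            cn = val * mult
            rows.append(
                {
                    "assay": genotype,
                    "sample_id": sample_id,
                    "day": day,
                    "depth": depth,
                    "cn_per_g": cn,
                    "sd": config.replicate_noise_cv * cn,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class CommunitySimConfig:
    """Dirichlet community-table generator settings.

    ``baseline`` maps taxa to baseline proportions (must sum to 1);
    ``group_effects`` adds a per-group shift to chosen taxa (renormalised
    afterwards); ``concentration`` controls within-group scatter (larger
    means tighter around the group composition).
    """

    n_samples_per_group: dict[str, int] = field(
        default_factory=lambda: {"surface": 5, "middle": 5, "bottom": 4}
    )
    baseline: dict[str, float] = field(
        default_factory=lambda: {
            "Chitinophagaceae": 0.12,
            "Acidobacteria_uncl": 0.09,
            "Planctomycetes": 0.10,
            "Rhizobiales_uncl": 0.06,
            "Sphingomonadaceae": 0.05,
            "Nocardioidaceae": 0.04,
            "Spartobacteria_uncl": 0.04,
            "Xanthomonadales_uncl": 0.04,
            "Nitrospira": 0.03,
            "Nitrosomonas": 0.005,
            "other": 0.425,
        }
    )
    group_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "surface": {
                "Planctomycetes": 0.06,
                "Chitinophagaceae": -0.05,
                "Sphingomonadaceae": -0.03,
                "other": 0.02,
            }
        }
    )
    concentration: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError("concentration must be > 0")
        total = sum(self.baseline.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"baseline proportions must sum to 1 (got {total})")
        if any(p < 0 for p in self.baseline.values()):
            raise ValueError("baseline proportions must be >= 0")
        for group, effects in self.group_effects.items():
            unknown = set(effects) - set(self.baseline)
            if unknown:
                raise ValueError(f"effects on unknown taxa {sorted(unknown)}")
            for taxon, eff in effects.items():
                if self.baseline[taxon] + eff < 0:
                    raise ValueError(
                        f"effect {eff} on {taxon!r} in group {group!r} pushes "
                        "its proportion below 0"
                    )
        if any(n < 1 for n in self.n_samples_per_group.values()):
            raise ValueError("each group needs >=1 sample")


def generate_community_table(config: CommunitySimConfig):
    """Sample x taxon proportion table with planted group structure.

    Returns a :class:`~rasbiofilter.community.CommunityTable`; every row
    sums to 1 and carries its group label.
    """
    from .community import CommunityTable

    rng = _child_rng(config.seed, _STREAM_COMMUNITY)
    taxa = list(config.baseline)
    base = np.array([config.baseline[t] for t in taxa])
    rows, ids, labels = [], [], []
    for group, n in config.n_samples_per_group.items():
        mean = base.copy()
        for taxon, eff in config.group_effects.get(group, {}).items():
            mean[taxa.index(taxon)] += eff
        mean = mean / mean.sum()
        pos = mean > 0
        alpha = config.concentration * mean[pos]
        draws = rng.dirichlet(alpha, size=n)
        for i in range(n):
            full = np.zeros(len(taxa))
            full[pos] = draws[i]
            rows.append(full)
            ids.append(f"{group}-{i}")
            labels.append(group)
    data = pd.DataFrame(rows, index=ids, columns=taxa)
    return CommunityTable(data, pd.Series(labels, index=ids, name="group"))
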