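"""End-to-end pipeline orchestration.

Stages (``simulate``, ``qpcr``, ``biomass``, ``correlate``, ``depth-test``,
``community``) share one config and one root seed; each stage reads its
declared inputs from the output directory and writes its declared outputs
there. Every CSV carries a header comment with the package version and a
hash of the config, and a manifest records content hashes of all
artifacts so reruns can be verified bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biomass import (
    AOMModelParams,
    delta_substrate,
    mcrt_sweep,
    model_observed_ratio,
    observed_aom_total,
)
from .community import (
    CommunityTable,
    bray_curtis,
    complete_linkage,
    dendrogram_to_newick,
    envfit_table,
    pcoa,
    permanova,
    within_group_similarity,
)
from .nitrifier_stats import correlation_matrix, depth_summary
from .qpcr import fit_standard_curve, quantify_samples
from .synthetic import (
    ChemistryConfig,
    CommunitySimConfig,
    MarkerSimConfig,
    generate_chemistry_series,
    generate_community_table,
    generate_marker_series,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "qpcr", "biomass", "correlate", "depth-test", "community")

#: Depth-category midpoints (m above the biofilter base), used as the
#: numeric environmental covariate for ordination vector fitting.
DEPTH_MIDPOINTS_M = {"surface": 1.37, "middle": 0.86, "bottom": 0.22}

# input files each stage requires (beyond the config itself)
_STAGE_INPUTS = {
    "simulate": (),
    "qpcr": ("qpcr_standards.csv", "qpcr_samples.csv"),
    "biomass": ("markers.csv",),
    "correlate": ("markers.csv",),
    "depth-test": ("markers.csv",),
    "community": ("community.csv", "metadata.csv"),
}


@dataclass
class PipelineConfig:
    """Single configuration object for all stages."""

    outdir: Path = Path("rasbiofilter-out")
    seed: int = 0
    n_perm: int = 999
    n_perm_correlation: int = 4999
    theta_x: float = 20.0
    log_level: str = "INFO"
    chemistry: dict[str, Any] = field(default_factory=dict)
    markers: dict[str, Any] = field(default_factory=dict)
    community: dict[str, Any] = field(default_factory=dict)
    model: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load from YAML (JSON is valid YAML)."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "outdir" in raw:
            raw["outdir"] = Path(raw["outdir"])
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["outdir"] = str(d["outdir"])
        return d

    @property
    def config_hash(self) -> str:
        """Hash of the scientific configuration (paths/logging excluded)."""
        d = self.to_dict()
        d.pop("outdir", None)
        d.pop("log_level", None)
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def chemistry_config(self) -> ChemistryConfig:
        return ChemistryConfig(**{"seed": self.seed, **self.chemistry})

    def marker_config(self) -> MarkerSimConfig:
        kw = dict(self.markers)
        for key in ("genotypes",):
            if key in kw:
                kw[key] = tuple(kw[key])
        return MarkerSimConfig(**{"seed": self.seed, **kw})

    def community_config(self) -> CommunitySimConfig:
        return CommunitySimConfig(**{"seed": self.seed, **self.community})

    def model_params(self) -> AOMModelParams:
        return AOMModelParams(**self.model)


def write_csv(df: pd.DataFrame, path: Path, config_hash: str, *, index: bool = False) -> None:
    """Write a CSV with a provenance header comment."""
    with open(path, "w") as fh:
        fh.write(f"# rasbiofilter {__version__} config={config_hash}\n")
        df.to_csv(fh, index=index)


def read_csv(path: str | Path, **kwargs: Any) -> pd.DataFrame:
    """Read a pipeline CSV, skipping provenance comments."""
    return pd.read_csv(path, comment="#", **kwargs)


def _require(outdir: Path, stage: str) -> None:
    missing = [f for f in _STAGE_INPUTS[stage] if not (outdir / f).exists()]
    if missing:
        raise FileNotFoundError(
            f"stage {stage!r} requires missing input(s): {missing} in {outdir}"
        )


def _stage_simulate(config: PipelineConfig, outdir: Path) -> list[Path]:
    h = config.config_hash
    chem = generate_chemistry_series(config.chemistry_config())
    markers = generate_marker_series(config.marker_config())
    table = generate_community_table(config.community_config())
    meta = pd.DataFrame(
        {
            "sample_id": table.sample_ids,
            "group": table.groups.to_numpy(),
            "depth_m": [DEPTH_MIDPOINTS_M.get(g, np.nan) for g in table.groups],
        }
    )
    standards, samples = _synthetic_qpcr_tables(markers, config.seed)
    outputs = {
        "chemistry.csv": chem,
        "markers.csv": markers,
        "qpcr_standards.csv": standards,
        "qpcr_samples.csv": samples,
        "metadata.csv": meta,
    }
    paths = []
    for name, df in outputs.items():
        write_csv(df, outdir / name, h)
        paths.append(outdir / name)
    write_csv(table.data, outdir / "community.csv", h, index=True)
    paths.append(outdir / "community.csv")
    return paths


def _synthetic_qpcr_tables(
    markers: pd.DataFrame, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Back-derive plausible qPCR raw tables from a marker table.

    Each assay gets a textbook calibration (slope -3.3219, i.e. 100%
    efficiency) over the 15 to 1.5e6 copies-per-reaction dynamic range,
    and each marker measurement is converted to a triplicate of Cq values
    through the default extraction geometry with small cycle noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 21)))
    slope, intercept = -3.3219, 38.0
    levels = [15.0 * 10**k for k in range(6)]
    std_rows = [
        {"assay": assay, "copies": lvl, "cq": slope * np.log10(lvl) + intercept}
        for assay in markers["assay"].unique()
        for lvl in levels
    ]
    sample_rows = []
    for r in markers.itertuples():
        copies_rxn = r.cn_per_g / 100.0  # invert default 100 uL/1 uL/1 g geometry
        cq = slope * np.log10(copies_rxn) + intercept
        for rep in range(3):
            sample_rows.append(
                {
                    "assay": r.assay,
                    "sample_id": r.sample_id,
                    "day": r.day,
                    "depth": r.depth,
                    "mass_g": 1.0,
                    "cq": cq + rng.normal(0.0, 0.05),
                }
            )
    return pd.DataFrame(std_rows), pd.DataFrame(sample_rows)


def _stage_qpcr(config: PipelineConfig, outdir: Path) -> list[Path]:
    standards = read_csv(outdir / "qpcr_standards.csv")
    samples = read_csv(outdir / "qpcr_samples.csv")
    curves = {
        assay: fit_standard_curve(list(zip(grp["copies"], grp["cq"])))
        for assay, grp in standards.groupby("assay")
    }
    quant = quantify_samples(samples, curves)
    write_csv(quant, outdir / "quant.csv", config.config_hash)
    return [outdir / "quant.csv"]


def _stage_biomass(config: PipelineConfig, outdir: Path) -> list[Path]:
    params = config.model_params()
    chem_path = outdir / "chemistry.csv"
    if chem_path.exists():
        chem = read_csv(chem_path)
        removals = np.array(
            [
                delta_substrate(i, e) if i >= e else 0.0
                for i, e in zip(chem["influent_ammonia"], chem["effluent_ammonia"])
            ]
        )
        ds_mean, ds_min, ds_max = (
            float(removals.mean()),
            float(removals.min()),
            float(removals.max()),
        )
        params = dataclasses.replace(params, delta_S_NH3=ds_mean)
    else:
        ds_mean = ds_min = ds_max = params.delta_S_NH3
    curve = mcrt_sweep(
        params, deltaS_min=ds_min, deltaS_mean=ds_mean, deltaS_max=ds_max
    )
    markers = read_csv(outdir / "markers.csv")
    observed_mean, _ = observed_aom_total(markers, params)
    ratio = model_observed_ratio(curve, observed_mean, config.theta_x)
    write_csv(curve.to_frame(), outdir / "biomass_curve.csv", config.config_hash)
    summary = {
        "theta_x_days": config.theta_x,
        "delta_S_mean_mg_per_L": ds_mean,
        "model_cells_per_g_at_theta_x": curve.at(config.theta_x),
        "observed_aom_cells_per_g": observed_mean,
        "model_observed_ratio": ratio,
        "config_hash": config.config_hash,
    }
    (outdir / "biomass_summary.json").write_text(json.dumps(summary, indent=2))
    return [outdir / "biomass_curve.csv", outdir / "biomass_summary.json"]


def _stage_correlate(config: PipelineConfig, outdir: Path) -> list[Path]:
    markers = read_csv(outdir / "markers.csv")
    ts = markers[markers["sample_id"].str.startswith("T")]
    if ts.empty:
        ts = markers
    corr = correlation_matrix(ts, config.n_perm_correlation, config.seed)
    write_csv(corr, outdir / "correlations.csv", config.config_hash)
    return [outdir / "correlations.csv"]


def _stage_depth_test(config: PipelineConfig, outdir: Path) -> list[Path]:
    markers = read_csv(outdir / "markers.csv")
    profile = markers[markers["sample_id"].str.startswith("D-")]
    if profile.empty:
        profile = markers
    summary = depth_summary(profile)
    tests = pd.DataFrame(
        [
            {"assay": a, "chi2": t.H, "df": t.df, "p": t.p}
            for a, t in summary.tests.items()
        ]
    )
    merged = summary.table.merge(tests, on="assay", how="left")
    write_csv(merged, outdir / "depth_summary.csv", config.config_hash)
    return [outdir / "depth_summary.csv"]


def _stage_community(config: PipelineConfig, outdir: Path) -> list[Path]:
    data = read_csv(outdir / "community.csv", index_col=0)
    meta = read_csv(outdir / "metadata.csv").set_index("sample_id")
    table = CommunityTable(data, meta["group"])
    dm = bray_curtis(table)
    merges = complete_linkage(dm)
    ordination = pcoa(dm)
    env_cols = [
        c for c in meta.columns if c != "group" and pd.api.types.is_numeric_dtype(meta[c])
    ]
    h = config.config_hash
    paths = []
    write_csv(dm.to_frame(), outdir / "distances.csv", h, index=True)
    paths.append(outdir / "distances.csv")
    ord_df = ordination.to_frame()
    write_csv(ord_df, outdir / "ordination.csv", h, index=True)
    paths.append(outdir / "ordination.csv")
    if env_cols:
        fit = envfit_table(ordination, meta[env_cols], config.n_perm, config.seed)
        write_csv(fit.reset_index(), outdir / "envfit.csv", h)
        paths.append(outdir / "envfit.csv")
    perm = permanova(dm, meta["group"], config.n_perm, config.seed)
    (outdir / "permanova.json").write_text(
        json.dumps(
            {
                "F": perm.F,
                "R2": perm.r_squared,
                "p": perm.p,
                "n_perm": perm.n_perm,
                "config_hash": h,
            },
            indent=2,
        )
    )
    paths.append(outdir / "permanova.json")
    (outdir / "dendrogram.nwk").write_text(dendrogram_to_newick(merges, dm.ids) + "\n")
    paths.append(outdir / "dendrogram.nwk")
    sim = within_group_similarity(dm, meta["group"])
    write_csv(sim.reset_index(), outdir / "similarity.csv", h)
    paths.append(outdir / "similarity.csv")
    return paths


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "qpcr": _stage_qpcr,
    "biomass": _stage_biomass,
    "correlate": _stage_correlate,
    "depth-test": _stage_depth_test,
    "community": _stage_community,
}


def run(
    config: PipelineConfig, stages: Sequence[str] | None = None
) -> dict[str, str]:
    """Run the requested stages in order; returns the artifact manifest.

    Stage inputs are checked before any computation; the manifest maps
    every written artifact to its SHA-256 content hash and is saved as
    ``manifest.json`` in the output directory.
    """
    stages = list(stages if stages is not None else STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}; valid: {list(STAGES)}")
    logging.basicConfig(level=config.log_level.upper())
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # fail fast on missing inputs, accounting for earlier stages' outputs
    will_exist = set()
    for stage in stages:
        needed = [
            f
            for f in _STAGE_INPUTS[stage]
            if f not in will_exist and not (outdir / f).exists()
        ]
        if needed:
            raise FileNotFoundError(
                f"stage {stage!r} requires missing input(s): {needed}"
            )
        if stage == "simulate":
            will_exist.update(
                {
                    "chemistry.csv",
                    "markers.csv",
                    "community.csv",
                    "metadata.csv",
                    "qpcr_standards.csv",
                    "qpcr_samples.csv",
                }
            )
    manifest: dict[str, str] = {}
    for stage in stages:
        logger.info("running stage %s", stage)
        _require(outdir, stage)
        for path in _STAGE_FUNCS[stage](config, outdir):
            manifest[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
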