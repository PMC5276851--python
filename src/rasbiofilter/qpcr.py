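"""Absolute quantification of marker genes from qPCR calibration data.

Standard curves regress quantification cycle (Cq) on log10 template copies;
amplification efficiency follows the amplification-factor convention
``E = 10**(-1/slope) - 1`` (1.0 means perfect doubling each cycle).
Unknowns are inverted through the curve and scaled from copies per reaction
to copy number per gram wet sand via the extraction geometry (elution
volume, template volume per reaction, sand mass extracted).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StandardCurve",
    "QuantResult",
    "fit_standard_curve",
    "quantify",
    "copies_per_gram",
    "replicate_summary",
    "quantify_samples",
]

#: Default extraction geometry: 100 uL elution, 1 uL template per reaction,
#: 1 g wet sand extracted. Override per assay when the kit workflow differs.
DEFAULT_ELUTION_UL = 100.0
DEFAULT_TEMPLATE_UL = 1.0
DEFAULT_MASS_G = 1.0


@dataclass(frozen=True)
class StandardCurve:
    """Linear qPCR calibration: ``Cq = slope * log10(copies) + intercept``.

    Attributes
    ----------
    slope : float
        Cq change per tenfold dilution; negative for a valid assay
        (more template -> earlier amplification).
    intercept : float
        Fitted Cq at one copy per reaction.
    efficiency : float
        ``10**(-1/slope) - 1``, as a fraction (1.0 = 100%).
    r_squared : float
        Coefficient of determination of the calibration fit.
    range_low, range_high : float
        Copies-per-reaction limits of the calibration dynamic range.
    """

    slope: float
    intercept: float
    efficiency: float
    r_squared: float
    range_low: float
    range_high: float

    @property
    def is_valid(self) -> bool:
        """A usable curve must have a negative slope."""
        return self.slope < 0


@dataclass(frozen=True)
class QuantResult:
    copies_per_reaction: float
    copies_per_gram: float
    in_range: bool


def fit_standard_curve(
    points: Sequence[tuple[float, float]],
) -> StandardCurve:
    """Fit a standard curve from ``(copies_per_reaction, Cq)`` pairs.

    Ordinary least squares of Cq on log10(copies). At least three distinct
    copy levels are required; all copy values must be positive.
    """
    pts = [(float(c), float(q)) for c, q in points]
    if any(c <= 0 for c, _ in pts):
        raise ValueError("standard-curve copy numbers must be > 0")
    levels = sorted({c for c, _ in pts})
    if len(levels) < 3:
        raise ValueError(
            f"need >=3 distinct copy levels to fit a standard curve, got {len(levels)}"
        )
    x = np.log10([c for c, _ in pts])
    y = np.asarray([q for _, q in pts])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    if slope < 0:
        eff = 10.0 ** (-1.0 / slope) - 1.0
    else:
        # Positive slope: physically meaningless calibration; flagged via
        # is_valid rather than raised so batch fits can continue.
        eff = float("nan")
    return StandardCurve(
        slope=float(slope),
        intercept=float(intercept),
        efficiency=float(eff),
        r_squared=r2,
        range_low=levels[0],
        range_high=levels[-1],
    )


def quantify(
    cq: float,
    curve: StandardCurve,
    *,
    elution_volume_ul: float = DEFAULT_ELUTION_UL,
    template_volume_ul: float = DEFAULT_TEMPLATE_UL,
    sample_mass_g: float = DEFAULT_MASS_G,
) -> QuantResult:
    """Invert a Cq value through the calibration.

    Out-of-range results (outside the calibration's dynamic range) are
    flagged via ``in_range``, not censored.
    """
    if not curve.is_valid:
        raise ValueError("cannot quantify with an invalid (non-negative-slope) curve")
    copies_rxn = 10.0 ** ((cq - curve.intercept) / curve.slope)
    # small relative slack so calibration endpoints round-trip in range
    in_range = bool(
        curve.range_low * (1 - 1e-9) <= copies_rxn <= curve.range_high * (1 + 1e-9)
    )
    cpg = copies_per_gram(
        copies_rxn, elution_volume_ul, template_volume_ul, sample_mass_g
    )
    return QuantResult(copies_rxn, cpg, in_range)


def copies_per_gram(
    copies_rxn: float,
    elution_volume: float,
    template_volume: float,
    sample_mass: float,
) -> float:
    """Scale copies per reaction to copies per gram of wet sand.

    ``copies_rxn * (elution_volume / template_volume) / sample_mass``;
    volumes must share a unit and cancel.
    """
    if elution_volume <= 0 or template_volume <= 0 or sample_mass <= 0:
        raise ValueError("elution volume, template volume and sample mass must be > 0")
    if copies_rxn < 0:
        raise ValueError("copies per reaction must be >= 0")
    return copies_rxn * (elution_volume / template_volume) / sample_mass


def replicate_summary(triplicate: Sequence[float]) -> tuple[float, float]:
    """Mean and sample SD (n-1 denominator) of technical replicates."""
    vals = np.asarray(triplicate, dtype=float)
    if vals.size < 2:
        raise ValueError("replicate summary needs >=2 values")
    return float(vals.mean()), float(vals.std(ddof=1))


def quantify_samples(
    samples: pd.DataFrame,
    curves: dict[str, StandardCurve],
    *,
    elution_volume_ul: float = DEFAULT_ELUTION_UL,
    template_volume_ul: float = DEFAULT_TEMPLATE_UL,
) -> pd.DataFrame:
    """Quantify a table of Cq measurements against per-assay curves.

    ``samples`` needs columns assay, sample_id, cq and optionally mass_g,
    day, depth. Replicate rows (same assay and sample) are summarised into
    mean copy number per gram plus replicate SD, giving the long marker
    table layout (assay, sample_id, day, depth, cn_per_g, sd).
    """
    required = {"assay", "sample_id", "cq"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"samples table missing columns: {sorted(missing)}")
    rows = []
    for (assay, sample_id), grp in samples.groupby(["assay", "sample_id"], sort=False):
        if assay not in curves:
            raise KeyError(f"no standard curve for assay {assay!r}")
        curve = curves[assay]
        mass = float(grp["mass_g"].iloc[0]) if "mass_g" in grp else DEFAULT_MASS_G
        per_rep = [
            quantify(
                cq,
                curve,
                elution_volume_ul=elution_volume_ul,
                template_volume_ul=template_volume_ul,
                sample_mass_g=mass,
            ).copies_per_gram
            for cq in grp["cq"]
        ]
        if len(per_rep) >= 2:
            mean, sd = replicate_summary(per_rep)
        else:
            mean, sd = per_rep[0], 0.0
        rows.append(
            {
                "assay": assay,
                "sample_id": sample_id,
                "day": grp["day"].iloc[0] if "day" in grp else math.nan,
                "depth": grp["depth"].iloc[0] if "depth" in grp else "surface",
                "cn_per_g": mean,
                "sd": sd,
            }
        )
    return pd.DataFrame(rows)
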