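"""Quantification and normalization of targeted lipidomics measurements.

Raw MRM peak areas are converted to amounts by single-point internal-standard
calibration::

    amount (umol) = peak_area / IS_peak_area * IS_concentration (umol/ml)
                    * resuspension_volume (ml)

Amounts are then normalized per sample to the sum of all polar lipids
(phospholipids + sphingolipids) detected in that sample, giving molar
fractions of total polar lipids (MFP).  Non-polar lipids (TAG, DAG, Cho, CE,
FFA, carnitines, CoAs) are expressed over the same polar denominator but do
not enter it, so the per-sample MFP of polar features always sums to 1.

The module also computes the membrane indices used to track fluidity across
development: per-class totals, the Total PL / Total SPL sums, the Cho/PL
ratio, and DPH fluorescence anisotropy with grating correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

from .nomenclature import ClassRegistry, default_registry, parse_lipid_name

__all__ = [
    "STAGE_LABELS",
    "STAGE_CODES",
    "LIPIDOME_STAGES",
    "DEFAULT_REPLICATES",
    "SampleMeta",
    "PeakRecord",
    "AbundanceMatrix",
    "AnisotropyMeasurement",
    "CalibrationError",
    "NormalizationError",
    "quantify_amount",
    "quantify_peak_table",
    "normalize_mfp",
    "class_totals",
    "cho_pl_ratio",
    "anisotropy",
]

# The 15 aligned developmental stages (embryonic day E*, postnatal day P*) and
# their integer time codes shared by the regression and GP modules.
STAGE_LABELS: tuple[str, ...] = (
    "E10.5", "E11.5", "E12.5", "E13.5", "E14.5", "E15.5", "E16.5", "E17.5",
    "E18.5", "P0", "P1", "P3", "P7", "P14", "P21",
)
STAGE_CODES: dict[str, int] = {lab: i + 1 for i, lab in enumerate(STAGE_LABELS)}

# The seven stages sampled in the lipidome time course, with replicate counts.
LIPIDOME_STAGES: tuple[str, ...] = ("E10.5", "E14.5", "E17.5", "P0", "P1", "P7", "P21")
DEFAULT_REPLICATES: dict[str, int] = {
    "E10.5": 5, "E14.5": 5, "E17.5": 5, "P0": 4, "P1": 4, "P7": 3, "P21": 3,
}

# Classes entering the Total PL and Total SPL sums.
TOTAL_PL_CLASSES: tuple[str, ...] = (
    "PC", "PE", "PI", "PS", "PA", "PG", "CL", "LBPA",
    "LPC", "LPE", "LPG", "LPS", "LPI", "LPA",
)
TOTAL_SPL_CLASSES: tuple[str, ...] = (
    "SM", "Cer", "GluCer", "GM3", "Gb3", "SL", "S1P", "LacCer", "Sph",
)


class CalibrationError(ValueError):
    """Internal-standard calibration failure (e.g. zero IS peak area)."""


class NormalizationError(ValueError):
    """MFP normalization failure (e.g. zero polar sum in a sample)."""


class Units(str, Enum):
    umol = "umol"
    MFP = "MFP"
    zscore = "zscore"
    log = "log"


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    stage_label: str
    replicate_index: int = 1

    def __post_init__(self) -> None:
        if self.stage_label not in STAGE_CODES:
            raise ValueError(
                f"unknown stage label {self.stage_label!r}; expected one of {STAGE_LABELS}"
            )

    @property
    def stage_code(self) -> int:
        return STAGE_CODES[self.stage_label]


@dataclass(frozen=True)
class PeakRecord:
    """One analyte measurement with its internal-standard calibration data."""

    sample_id: str
    analyte: str
    peak_area: float
    internal_standard: str
    is_concentration: float  # umol/ml
    is_peak_area: float
    resuspension_volume: float  # ml

    def __post_init__(self) -> None:
        if self.peak_area < 0:
            raise ValueError(f"negative peak area for {self.analyte} in {self.sample_id}")
        if self.is_concentration <= 0:
            raise ValueError(
                f"IS concentration must be > 0 ({self.internal_standard}, {self.sample_id})"
            )
        if self.resuspension_volume <= 0:
            raise ValueError(f"resuspension volume must be > 0 ({self.sample_id})")


def quantify_amount(record: PeakRecord) -> float:
    """Amount of the analyte in umol by internal-standard calibration."""
    if record.is_peak_area == 0:
        raise CalibrationError(
            f"zero internal-standard peak area for {record.internal_standard!r} "
            f"in sample {record.sample_id!r}"
        )
    return (
        record.peak_area
        / record.is_peak_area
        * record.is_concentration
        * record.resuspension_volume
    )


@dataclass
class AbundanceMatrix:
    """Features x samples abundance grid with per-sample stage metadata.

    ``values`` is a DataFrame whose index holds feature (lipid/gene) names and
    whose columns are sample ids, aligned with ``samples``.  Missing values
    (analyte not detected in a sample) are NaN and stay NaN through
    normalization; a measured zero is 0.
    """

    values: pd.DataFrame
    samples: tuple[SampleMeta, ...]
    units: Units = Units.umol
    transforms: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if list(self.values.columns) != ids:
            raise ValueError("sample metadata does not align with matrix columns")
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids")
        dup = self.values.index[self.values.index.duplicated()].tolist()
        if dup:
            raise ValueError(f"duplicate feature names: {dup}")
        if self.units in (Units.umol, Units.MFP):
            if (self.values.to_numpy() < 0).any():
                raise ValueError(f"negative values in {self.units.value} units")

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    @property
    def stage_codes(self) -> np.ndarray:
        return np.array([s.stage_code for s in self.samples])

    @property
    def stage_labels(self) -> list[str]:
        return [s.stage_label for s in self.samples]

    def stage_medians(self) -> pd.DataFrame:
        """Per-feature medians over replicates, columns ordered by stage code."""
        return self._stage_summary("median")

    def stage_means(self) -> pd.DataFrame:
        return self._stage_summary("mean")

    def _stage_summary(self, how: str) -> pd.DataFrame:
        codes = self.stage_codes
        order = sorted(set(codes))
        cols = {}
        for c in order:
            block = self.values.loc[:, codes == c]
            cols[c] = block.median(axis=1) if how == "median" else block.mean(axis=1)
        return pd.DataFrame(cols)

    def log_transform(self, pseudocount: float = 0.0) -> "AbundanceMatrix":
        if self.units not in (Units.umol, Units.MFP):
            raise ValueError(f"log transform expects umol/MFP input, got {self.units.value}")
        vals = np.log10(self.values + pseudocount)
        return replace(
            self, values=vals, units=Units.log, transforms=self.transforms + ("log10",)
        )

    def zscore(self) -> "AbundanceMatrix":
        """Per-feature centering and scaling across samples."""
        v = self.values
        sd = v.std(axis=1, ddof=1)
        sd = sd.replace(0.0, np.nan)
        z = v.sub(v.mean(axis=1), axis=0).div(sd, axis=0)
        return replace(
            self, values=z, units=Units.zscore, transforms=self.transforms + ("zscore",)
        )

    def min_presence_filter(self, min_fraction: float = 0.8) -> "AbundanceMatrix":
        """Drop features observed (non-missing) in fewer than ``min_fraction`` of samples.

        The default of 0.8 is a documented choice, not inferred from any
        source data; the threshold is exposed so stricter/looser policies can
        be applied explicitly.
        """
        keep = self.values.notna().mean(axis=1) >= min_fraction
        return replace(self, values=self.values.loc[keep])


def quantify_peak_table(
    peaks: pd.DataFrame, registry: ClassRegistry | None = None
) -> AbundanceMatrix:
    """Convert a long-format peak table to a feature x sample umol matrix.

    Expected columns: sample_id, analyte, peak_area, internal_standard,
    is_concentration_umol_per_ml, is_peak_area, resuspension_volume_ml, plus
    stage_label and replicate_index for the sample metadata.
    Absent (sample, analyte) pairs become missing values, not zeros.
    """
    required = {
        "sample_id", "analyte", "peak_area", "internal_standard",
        "is_concentration_umol_per_ml", "is_peak_area", "resuspension_volume_ml",
        "stage_label",
    }
    missing = required - set(peaks.columns)
    if missing:
        raise ValueError(f"peak table missing columns: {sorted(missing)}")
    amounts = []
    for row in peaks.itertuples(index=False):
        rec = PeakRecord(
            sample_id=row.sample_id,
            analyte=row.analyte,
            peak_area=row.peak_area,
            internal_standard=row.internal_standard,
            is_concentration=row.is_concentration_umol_per_ml,
            is_peak_area=row.is_peak_area,
            resuspension_volume=row.resuspension_volume_ml,
        )
        amounts.append(quantify_amount(rec))
    df = peaks[["analyte", "sample_id"]].copy()
    df["amount"] = amounts
    wide = df.pivot(index="analyte", columns="sample_id", values="amount")
    meta = (
        peaks[["sample_id", "stage_label"]]
        .assign(replicate_index=peaks.get("replicate_index", 1))
        .drop_duplicates("sample_id")
    )
    metas = [
        SampleMeta(r.sample_id, r.stage_label, int(r.replicate_index))
        for r in meta.itertuples(index=False)
    ]
    metas.sort(key=lambda m: (m.stage_code, m.replicate_index, m.sample_id))
    wide = wide.loc[:, [m.sample_id for m in metas]]
    wide = wide.loc[sorted(wide.index)]
    return AbundanceMatrix(wide, tuple(metas), Units.umol)


def _polar_mask(features: Sequence[str], registry: ClassRegistry) -> np.ndarray:
    return np.array(
        [parse_lipid_name(f, registry).is_polar for f in features], dtype=bool
    )


def normalize_mfp(
    matrix: AbundanceMatrix, registry: ClassRegistry | None = None
) -> AbundanceMatrix:
    """Normalize a umol matrix to molar fractions of total polar lipids.

    Every value is divided by its sample's sum over polar (phospholipid +
    sphingolipid) features; non-polar features use the same denominator but do
    not contribute to it.  Missing values are ignored in the denominator and
    stay missing.
    """
    if matrix.units is not Units.umol:
        raise ValueError(f"MFP normalization expects umol input, got {matrix.units.value}")
    registry = registry or default_registry()
    polar = _polar_mask(matrix.features, registry)
    if not polar.any():
        raise NormalizationError("no polar features in matrix")
    denom = matrix.values.loc[polar].sum(axis=0, skipna=True)
    zero = denom[denom <= 0]
    if len(zero):
        raise NormalizationError(
            f"zero polar lipid sum in sample(s): {list(zero.index)}"
        )
    vals = matrix.values.div(denom, axis=1)
    return replace(matrix, values=vals, units=Units.MFP)


def class_totals(
    matrix: AbundanceMatrix, registry: ClassRegistry | None = None
) -> pd.DataFrame:
    """Per-sample sums for every lipid class plus TotalPL and TotalSPL.

    TotalPL = PC+PE+PI+PS+PA+PG+CL+LBPA+LPC+LPE+LPG+LPS+LPI+LPA;
    TotalSPL = SM+Cer+GluCer+GM3+Gb3+SL+S1P+LacCer+Sph.  Cholesterol and the
    other neutral classes belong to neither sum.
    Returns a DataFrame indexed by class name (and the two totals), columns =
    samples.
    """
    registry = registry or default_registry()
    cls = pd.Series(
        [parse_lipid_name(f, registry).lipid_class for f in matrix.features],
        index=matrix.values.index,
    )
    per_class = matrix.values.groupby(cls).sum(min_count=1)
    pl = per_class.reindex(TOTAL_PL_CLASSES).sum(axis=0, skipna=True)
    spl = per_class.reindex(TOTAL_SPL_CLASSES).sum(axis=0, skipna=True)
    out = per_class.copy()
    out.loc["TotalPL"] = pl
    out.loc["TotalSPL"] = spl
    return out


def cho_pl_ratio(
    matrix: AbundanceMatrix, registry: ClassRegistry | None = None
) -> pd.Series:
    """Per-sample free cholesterol / total phospholipid ratio."""
    totals = class_totals(matrix, registry)
    if "Cho" not in totals.index:
        raise ValueError("no cholesterol (Cho) feature in matrix")
    pl = totals.loc["TotalPL"]
    if (pl <= 0).any():
        bad = list(pl.index[pl <= 0])
        raise ValueError(f"zero total phospholipid in sample(s): {bad}")
    return totals.loc["Cho"] / pl


@dataclass(frozen=True)
class AnisotropyMeasurement:
    """DPH fluorescence anisotropy with grating correction.

    G = I_hv / I_hh corrects the instrument's polarization response;
    gamma = (I_vv - G*I_vh) / (I_vv + 2*G*I_vh) is the anisotropy, bounded in
    (-0.5, 1] for physical intensities.  Lower gamma means a more fluid
    membrane.
    """

    I_vv: float
    I_vh: float
    I_hv: float
    I_hh: float

    def __post_init__(self) -> None:
        for name in ("I_vv", "I_vh", "I_hv", "I_hh"):
            if getattr(self, name) <= 0:
                raise ValueError(f"intensity {name} must be > 0")

    @property
    def G(self) -> float:
        return self.I_hv / self.I_hh

    @property
    def gamma(self) -> float:
        g = self.G
        return (self.I_vv - g * self.I_vh) / (self.I_vv + 2 * g * self.I_vh)


def anisotropy(I_vv: float, I_vh: float, I_hv: float, I_hh: float) -> AnisotropyMeasurement:
    """Build an :class:`AnisotropyMeasurement` from the four polarized intensities."""
    return AnisotropyMeasurement(I_vv, I_vh, I_hv, I_hh)
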