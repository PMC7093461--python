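"""Absolute quantification of accepted identifications.

Each lipid subclass carries a deuterated internal standard (IS) of known
spiked amount; a species' amount is its peak area relative to the IS area of
its subclass, times the spiked amount (single-point, response factor 1).
Cholesterol may instead be interpolated from an external calibration curve of
analyte/IS response ratio versus concentration, with the high end of the
linear range triggering the dilute-and-reanalyze rule.  Amounts are converted
from micrograms to picomoles via the species' average molecular weight and
normalized to the sample's protein amount.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .errors import ConfigurationError, ValidationError
from .features import Feature, SampleMeta
from .identify import Identification
from .library import SpectralLibrary


@dataclass
class CalibrationCurve:
    levels: list[tuple[float, float]]  # (concentration ug/mL, response ratio)
    slope: float
    intercept: float
    linear_min: float
    linear_max: float

    def __post_init__(self):
        if len({c for c, _ in self.levels}) < 2:
            raise ValidationError("calibration needs >= 2 distinct concentrations")
        if not self.linear_min < self.linear_max:
            raise ValidationError("linear_min must be < linear_max")
        if not math.isfinite(self.slope):
            raise ValidationError("slope must be finite")


@dataclass
class QuantRecord:
    sample_id: str
    species_id: str
    subclass: str
    amount_pmol: float
    amount_per_protein: float  # pmol per ug protein
    out_of_range: bool = False
    dilution_applied: float = 1.0
    error: str | None = None


def quantify_by_internal_standard(
    analyte_area: float,
    is_area: float,
    is_amount: float,
    analyte_mw: float,
    is_mw: float,
) -> float:
    """Single-point IS quantification; returns the analyte amount in pmol.

    amount_ug = (analyte_area / is_area) * is_amount;
    pmol = amount_ug / analyte_mw * 1e6.  The IS itself quantifies to exactly
    its spiked amount (area ratio 1).
    """
    if is_area <= 0:
        raise ValidationError("internal-standard area must be > 0")
    if is_amount <= 0:
        raise ValidationError("internal-standard amount must be > 0")
    if analyte_mw <= 0 or is_mw <= 0:
        raise ValidationError("molecular weights must be > 0")
    amount_ug = (analyte_area / is_area) * is_amount
    return amount_ug / analyte_mw * 1e6


def fit_calibration(
    levels: list[tuple[float, float]],
    linear_min: float | None = None,
    linear_max: float | None = None,
) -> CalibrationCurve:
    """OLS line of response ratio on concentration over the calibration levels."""
    concs = [c for c, _ in levels]
    if len(set(concs)) < 2:
        raise ValidationError("calibration needs >= 2 distinct concentrations")
    if len(levels) == 2:
        # exact line through two points (linregress is equivalent but this
        # keeps the two-point case free of any least-squares rounding)
        (c0, r0), (c1, r1) = levels
        slope = (r1 - r0) / (c1 - c0)
        intercept = r0 - slope * c0
    else:
        result = stats.linregress(concs, [r for _, r in levels])
        slope, intercept = float(result.slope), float(result.intercept)
    return CalibrationCurve(
        levels=list(levels),
        slope=slope,
        intercept=intercept,
        linear_min=min(concs) if linear_min is None else linear_min,
        linear_max=max(concs) if linear_max is None else linear_max,
    )


def quantify_by_calibration(
    analyte_area: float,
    is_area: float,
    curve: CalibrationCurve,
    dilution_factor: float = 1.0,
) -> tuple[float, bool]:
    """Interpolate a concentration (ug/mL) from the calibration curve.

    Returns (concentration corrected for dilution, out_of_range flag).  The
    flag reflects the undiluted interpolation: above linear_max it marks the
    sample for dilute-and-reanalyze; below linear_min it flags an
    extrapolated low value (reported as-is).
    """
    if is_area <= 0:
        raise ValidationError("internal-standard area must be > 0")
    if dilution_factor < 1:
        raise ValidationError("dilution factor must be >= 1")
    if curve.slope == 0:
        raise ValidationError("calibration slope is zero; cannot invert")
    response_ratio = analyte_area / is_area
    interpolated = (response_ratio - curve.intercept) / curve.slope
    out_of_range = interpolated > curve.linear_max or interpolated < curve.linear_min
    return interpolated * dilution_factor, out_of_range


def build_quant_table(
    identifications: list[Identification],
    features: list[Feature],
    samples: list[SampleMeta],
    library: SpectralLibrary,
    calibration_curves: dict[str, CalibrationCurve] | None = None,
) -> list[QuantRecord]:
    """One QuantRecord per accepted analyte identification.

    Internal-standard features are used as the per-subclass denominators and
    excluded from the analyte table.  A subclass whose IS is unusable in a
    sample yields records with NaN amounts and an error message (recorded,
    not silently dropped); a subclass with neither an IS spike nor a
    calibration curve raises ConfigurationError.
    """
    calibration_curves = calibration_curves or {}
    feat_by_id = {f.feature_id: f for f in features}
    meta_by_id = {s.sample_id: s for s in samples}

    accepted = [i for i in identifications if i.accepted]
    # per (sample, subclass): area of the IS feature
    is_area: dict[tuple[str, str], float] = {}
    analytes: list[tuple[Identification, Feature]] = []
    for ident in accepted:
        feature = feat_by_id.get(ident.feature_id)
        if feature is None:
            continue
        species = library.species[ident.species_id]
        if species.is_internal_standard:
            is_area[(feature.sample_id, species.subclass)] = feature.area
        else:
            analytes.append((ident, feature))

    records: list[QuantRecord] = []
    for ident, feature in analytes:
        species = library.species[ident.species_id]
        meta = meta_by_id.get(feature.sample_id)
        if meta is None:
            raise ConfigurationError(f"no sample metadata for {feature.sample_id!r}")
        subclass = species.subclass
        spiked = meta.is_spikes.get(subclass)
        curve = calibration_curves.get(subclass)
        if spiked is None and curve is None:
            raise ConfigurationError(
                f"subclass {subclass!r} has neither an IS spike nor a calibration "
                f"curve in sample {meta.sample_id!r}"
            )
        area_is = is_area.get((feature.sample_id, subclass), 0.0)
        record = QuantRecord(
            sample_id=feature.sample_id,
            species_id=species.species_id,
            subclass=subclass,
            amount_pmol=math.nan,
            amount_per_protein=math.nan,
            dilution_applied=meta.dilution_factor,
        )
        if area_is <= 0:
            record.error = (
                f"internal standard for subclass {subclass!r} missing or zero "
                f"in sample {meta.sample_id!r}"
            )
            records.append(record)
            continue
        is_species = _internal_standard_species(library, subclass)
        if curve is not None:
            conc, oor = quantify_by_calibration(
                feature.area, area_is, curve, meta.dilution_factor
            )
            amount_ug = conc * meta.extract_volume_ml
            record.out_of_range = oor
            record.amount_pmol = amount_ug / species.average_mw * 1e6
        else:
            record.amount_pmol = quantify_by_internal_standard(
                feature.area,
                area_is,
                spiked,
                species.average_mw,
                is_species.average_mw if is_species is not None else species.average_mw,
            )
        record.amount_per_protein = record.amount_pmol / meta.protein_amount
        records.append(record)
    return records


def _internal_standard_species(library: SpectralLibrary, subclass: str):
    for sp in library.species.values():
        if sp.is_internal_standard and sp.subclass == subclass:
            return sp
    return None


def write_quant_table(records: list[QuantRecord], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "species_id": r.species_id,
                "subclass": r.subclass,
                "amount_pmol": repr(r.amount_pmol),
                "amount_pmol_per_ug_protein": repr(r.amount_per_protein),
                "out_of_range": int(r.out_of_range),
                "dilution_applied": repr(r.dilution_applied),
                "error": r.error or "",
            }
            for r in records
        ],
        columns=["sample_id", "species_id", "subclass", "amount_pmol",
                 "amount_pmol_per_ug_protein", "out_of_range", "dilution_applied",
                 "error"],
    ).to_csv(path, sep="\t", index=False)


def read_quant_table(path) -> list[QuantRecord]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "species_id": str},
                     keep_default_na=False, float_precision="round_trip")
    return [
        QuantRecord(
            sample_id=r.sample_id,
            species_id=r.species_id,
            subclass=r.subclass,
            amount_pmol=float(r.amount_pmol),
            amount_per_protein=float(r.amount_pmol_per_ug_protein),
            out_of_range=bool(int(r.out_of_range)),
            dilution_applied=float(r.dilution_applied),
            error=r.error or None,
        )
        for r in df.itertuples(index=False)
    ]
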