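"""Experimental inputs: detected LC-MS feature tables, MS/MS spectra, sample metadata.

The pipeline starts downstream of peak detection/alignment: its inputs are a
per-sample feature table (TSV) with attached data-dependent MS/MS spectra
(MGF, TITLE = feature_id) and a sample-metadata config (YAML) carrying group
labels, protein amounts, dilution factors and the internal-standard spike
panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from pyteomics import mgf

from .errors import ValidationError
from .library import SUBCLASSES, FragmentPeak

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = ["feature_id", "sample_id", "mz", "rt", "area"]

# Deuterated internal-standard spike panels, in micrograms per sample.
# The raft and non-raft panels differ only in the Cer and SM spike levels.
RAFT_SPIKES = {
    "PC": 1.5, "PE": 0.5, "PG": 0.25, "PS": 0.5, "PI": 0.5, "PA": 0.05,
    "Cer": 0.2, "SM": 0.05, "LPC": 0.02, "LPE": 0.02, "TG": 10.0, "Chol": 2.0,
}
NONRAFT_SPIKES = dict(RAFT_SPIKES, Cer=0.02, SM=0.01)


@dataclass
class Spectrum:
    """An MS/MS spectrum; peaks are kept sorted ascending by m/z."""

    peaks: list[FragmentPeak]
    mode: str
    precursor_mz: float

    def __post_init__(self):
        if not self.peaks:
            raise ValidationError("spectrum needs at least one peak")
        if self.mode not in ("positive", "negative"):
            raise ValidationError(f"mode must be positive/negative, got {self.mode!r}")
        if self.precursor_mz <= 0:
            raise ValidationError("precursor m/z must be > 0")
        self.peaks = sorted(self.peaks, key=lambda p: p.mz)

    @property
    def mz_array(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks])

    @property
    def intensity_array(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks])


@dataclass
class Feature:
    """One detected LC-MS feature, optionally with its best MS/MS spectrum."""

    feature_id: str
    sample_id: str
    mz: float
    rt: float
    area: float
    ms2: Spectrum | None = None

    def __post_init__(self):
        if self.mz <= 0:
            raise ValidationError("feature m/z must be > 0")
        if self.rt < 0:
            raise ValidationError("feature RT must be >= 0")
        if self.area < 0:
            raise ValidationError("feature area must be >= 0")


@dataclass
class SampleMeta:
    sample_id: str
    group: str  # raft | nonraft | other
    protein_amount: float  # micrograms
    dilution_factor: float = 1.0
    is_spikes: dict[str, float] = field(default_factory=dict)  # subclass -> micrograms
    extract_volume_ml: float = 0.1  # reconstitution volume for calibration-based quant

    def __post_init__(self):
        if self.group not in ("raft", "nonraft", "other"):
            raise ValidationError(f"group must be raft/nonraft/other, got {self.group!r}")
        if self.protein_amount <= 0:
            raise ValidationError("protein amount must be > 0")
        if self.dilution_factor < 1:
            raise ValidationError("dilution factor must be >= 1")
        for sc in self.is_spikes:
            if sc not in SUBCLASSES:
                raise ValidationError(f"unknown subclass in spike panel: {sc!r}")


# ---------------------------------------------------------------------------
# feature table + MGF I/O

def _charge_to_mode(charge) -> str:
    # pyteomics parses CHARGE=1+ / 1- into signed Charge integers
    if isinstance(charge, (list, tuple, np.ndarray)):
        charge = charge[0]
    return "positive" if int(charge) > 0 else "negative"


def read_spectra(spectra_path) -> dict[str, Spectrum]:
    """Read an MGF file into spectra keyed by TITLE (= feature_id)."""
    spectra: dict[str, Spectrum] = {}
    with mgf.MGF(str(spectra_path)) as reader:
        for spec in reader:
            params = spec["params"]
            title = str(params["title"])
            if title in spectra:
                raise ValidationError(f"duplicate spectrum TITLE {title!r}")
            peaks = [
                FragmentPeak(float(m), float(i))
                for m, i in zip(spec["m/z array"], spec["intensity array"])
            ]
            spectra[title] = Spectrum(
                peaks=peaks,
                mode=_charge_to_mode(params.get("charge", [1])),
                precursor_mz=float(np.atleast_1d(params["pepmass"])[0]),
            )
    return spectra


def read_features(table_path, spectra_path=None) -> list[Feature]:
    """Read a feature TSV and attach MS/MS spectra by feature_id.

    Every row yields a feature or a logged reject; spectra whose TITLE matches
    no feature are ignored with a warning.
    """
    df = pd.read_csv(table_path, sep="\t", dtype={"feature_id": str, "sample_id": str},
                     float_precision="round_trip")
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"feature table missing column(s): {', '.join(missing)}")
    spectra = read_spectra(spectra_path) if spectra_path is not None else {}
    features: list[Feature] = []
    for row in df.itertuples(index=False):
        try:
            features.append(
                Feature(
                    feature_id=row.feature_id,
                    sample_id=row.sample_id,
                    mz=float(row.mz),
                    rt=float(row.rt),
                    area=float(row.area),
                    ms2=spectra.pop(row.feature_id, None),
                )
            )
        except (ValidationError, ValueError) as exc:
            logger.warning("rejected feature row %r: %s", row.feature_id, exc)
    if spectra:
        logger.warning("%d MGF spectra matched no feature and were ignored", len(spectra))
    return features


def write_features(features: list[Feature], table_path, spectra_path=None) -> None:
    """Write the feature TSV and (if a path is given) the MGF spectra file."""
    df = pd.DataFrame(
        [
            {
                "feature_id": f.feature_id,
                "sample_id": f.sample_id,
                "mz": repr(f.mz),
                "rt": repr(f.rt),
                "area": repr(f.area),
            }
            for f in features
        ],
        columns=FEATURE_COLUMNS,
    )
    df.to_csv(table_path, sep="\t", index=False)
    if spectra_path is None:
        return
    records = []
    for f in features:
        if f.ms2 is None:
            continue
        records.append(
            {
                "m/z array": f.ms2.mz_array,
                "intensity array": f.ms2.intensity_array,
                "params": {
                    "title": f.feature_id,
                    "pepmass": f.ms2.precursor_mz,
                    "charge": "1+" if f.ms2.mode == "positive" else "1-",
                },
            }
        )
    mgf.write(records, str(spectra_path), fragment_format="%.10g %.10g",
              write_charges=False, file_mode="w")


# ---------------------------------------------------------------------------
# sample metadata

def read_sample_meta(config_path) -> list[SampleMeta]:
    """Read sample metadata from YAML, filling spike-panel defaults by group."""
    with open(config_path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    return sample_meta_from_dict(cfg)


def sample_meta_from_dict(cfg: dict) -> list[SampleMeta]:
    samples = []
    for entry in cfg.get("samples", []):
        group = entry.get("group", "other")
        defaults = NONRAFT_SPIKES if group == "nonraft" else RAFT_SPIKES
        spikes = dict(defaults)
        spikes.update(entry.get("is_spikes") or {})
        samples.append(
            SampleMeta(
                sample_id=str(entry["sample_id"]),
                group=group,
                protein_amount=float(entry["protein_amount"]),
                dilution_factor=float(entry.get("dilution_factor", 1.0)),
                is_spikes=spikes,
                extract_volume_ml=float(entry.get("extract_volume_ml", 0.1)),
            )
        )
    return samples


def write_sample_meta(samples: list[SampleMeta], path) -> None:
    cfg = {
        "samples": [
            {
                "sample_id": s.sample_id,
                "group": s.group,
                "protein_amount": s.protein_amount,
                "dilution_factor": s.dilution_factor,
                "is_spikes": dict(s.is_spikes),
                "extract_volume_ml": s.extract_volume_ml,
            }
            for s in samples
        ]
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
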