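"""Feature-to-library matching: accurate mass, spectral similarity, RT similarity.

Identification proceeds in three stages, mirroring standard practice for
in-silico-library lipid annotation:

1. accurate-mass search of the library at a ppm precursor tolerance;
2. weighted reverse dot-product MS/MS similarity between the experimental
   spectrum and each candidate's library spectrum,

   .. math::

      S = \\frac{\\sum_k (I_{D,k}^n\\,mz_{D,k}^m)(I_{E,k}^n\\,mz_{E,k}^m)}
               {\\sqrt{\\sum_k (I_{D,k}^n mz_{D,k}^m)^2\\;\\sum_k (I_{E,k}^n mz_{E,k}^m)^2}}

   where the sum runs over the library (D) fragments only — experimental
   peaks not near any library fragment are ignored ("reverse" match) — with
   mz weight m and intensity weight n (n differs between ion modes);
3. a trapezoidal retention-time similarity in |RT_exp - RT_pred| with a
   full-score plateau and a linear flank to zero.

A candidate is kept when its spectral score exceeds the spectral threshold
and accepted when its RT score also exceeds the RT threshold; at most one
identification is accepted per feature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .features import Feature, Spectrum
from .library import LibraryEntry, SpectralLibrary


@dataclass
class ScoringParams:
    """All identification thresholds and tolerances in one configurable place."""

    mz_weight_m: float = 1.0
    intensity_weight_n_pos: float = 0.6
    intensity_weight_n_neg: float = 1.0
    spectral_threshold: float = 0.8
    rt_threshold: float = 0.5
    precursor_tol_ppm: float = 10.0
    fragment_tol_da: float = 0.02
    rt_plateau_a: float = 0.15  # minutes: |dRT| below this scores 1
    rt_zero_b: float = 0.5  # minutes: |dRT| beyond this scores 0

    def __post_init__(self):
        if not (0 < self.spectral_threshold <= 1):
            raise ValidationError("spectral_threshold must be in (0, 1]")
        if not (0 < self.rt_threshold <= 1):
            raise ValidationError("rt_threshold must be in (0, 1]")
        if not (0 < self.rt_plateau_a < self.rt_zero_b):
            raise ValidationError("need 0 < rt_plateau_a < rt_zero_b")
        if self.precursor_tol_ppm <= 0 or self.fragment_tol_da <= 0:
            raise ValidationError("tolerances must be > 0")

    def intensity_weight(self, mode: str) -> float:
        return self.intensity_weight_n_pos if mode == "positive" else self.intensity_weight_n_neg


@dataclass
class Identification:
    """A scored feature-library match; ``accepted`` marks the per-feature winner."""

    feature_id: str
    library_key: tuple[str, str, str]  # (species_id, mode, adduct)
    mass_error_ppm: float
    spectral_score: float
    rt_score: float
    accepted: bool

    @property
    def species_id(self) -> str:
        return self.library_key[0]


def match_mass(
    feature: Feature, library: SpectralLibrary, params: ScoringParams
) -> list[LibraryEntry]:
    """Accurate-mass candidate search, sorted by |mass error| ascending.

    When the feature carries an MS/MS spectrum its ion mode restricts the
    search; otherwise both modes are searched.
    """
    if feature.mz <= 0:
        raise ValidationError("feature m/z must be > 0")
    mode = feature.ms2.mode if feature.ms2 is not None else None
    hits = []
    for entry in library.entries:
        if mode is not None and entry.mode != mode:
            continue
        err_ppm = abs(entry.precursor_mz - feature.mz) / entry.precursor_mz * 1e6
        if err_ppm <= params.precursor_tol_ppm:
            hits.append((err_ppm, entry))
    hits.sort(key=lambda t: (t[0], t[1].species_id, t[1].adduct))
    return [entry for _, entry in hits]


def spectral_similarity(
    experimental: Spectrum, reference: Spectrum, params: ScoringParams
) -> float:
    """Weighted reverse dot-product similarity in [0, 1].

    Only the reference (library) fragments participate: each is matched to
    the experimental peaks within ``fragment_tol_da``; multiple matches are
    intensity-summed and their m/z intensity-averaged.  Returns exactly 1 for
    a perfect match and 0 when no reference fragment is matched.
    """
    if not reference.peaks:
        raise ValidationError("reference spectrum is empty")
    if experimental.mode != reference.mode:
        raise ValidationError("experimental and reference spectra differ in ion mode")
    m = params.mz_weight_m
    n = params.intensity_weight(reference.mode)
    tol = params.fragment_tol_da

    exp_mz = experimental.mz_array
    exp_int = experimental.intensity_array

    w_ref = np.empty(len(reference.peaks))
    w_exp = np.empty(len(reference.peaks))
    for k, peak in enumerate(reference.peaks):
        idx = np.nonzero(np.abs(exp_mz - peak.mz) <= tol)[0]
        i_e = float(exp_int[idx].sum())
        if i_e > 0:
            if len(idx) == 1:  # avoid a 1-ulp rounding in the weighted mean
                mz_e = float(exp_mz[idx[0]])
            else:
                mz_e = float(np.average(exp_mz[idx], weights=exp_int[idx]))
        else:
            mz_e = peak.mz  # convention: unmatched fragments carry the library m/z
        w_ref[k] = peak.intensity**n * peak.mz**m
        w_exp[k] = i_e**n * mz_e**m

    if np.array_equal(w_ref, w_exp):
        # identical weight vectors: the cosine is 1 by definition; bypass the
        # 1-ulp rounding of sqrt(x*x) so a perfect match scores exactly 1
        return 1.0 if np.any(w_ref) else 0.0
    denom = float(np.linalg.norm(w_ref) * np.linalg.norm(w_exp))
    if denom == 0.0:
        return 0.0
    score = float(w_ref @ w_exp) / denom
    return min(max(score, 0.0), 1.0)


def rt_similarity(rt_exp: float, rt_pred: float, params: ScoringParams) -> float:
    """Trapezoidal RT similarity: 1 on the plateau, linear flank, 0 beyond b."""
    if rt_exp < 0 or rt_pred < 0:
        raise ValidationError("retention times must be >= 0")
    d = abs(rt_exp - rt_pred)
    a, b = params.rt_plateau_a, params.rt_zero_b
    if d <= a:
        return 1.0
    if d >= b:
        return 0.0
    return (b - d) / (b - a)


def identify(
    features: list[Feature],
    library: SpectralLibrary,
    params: ScoringParams | None = None,
) -> list[Identification]:
    """Score all mass-matched candidates per feature and accept at most one.

    Candidates passing the spectral threshold are ranked by spectral score
    (ties: smaller |mass error|, then species_id); the best one is accepted
    iff its RT score also clears the RT threshold.  All scored candidates are
    returned for audit, accepted or not.
    """
    if params is None:
        params = ScoringParams()
    if len(library) == 0:
        raise ValidationError("library is empty")
    out: list[Identification] = []
    for feature in features:
        if feature.ms2 is None:
            continue
        candidates = match_mass(feature, library, params)
        scored: list[Identification] = []
        for entry in candidates:
            ref = Spectrum(
                peaks=list(entry.fragments), mode=entry.mode,
                precursor_mz=entry.precursor_mz,
            )
            ident = Identification(
                feature_id=feature.feature_id,
                library_key=entry.key,
                mass_error_ppm=(feature.mz - entry.precursor_mz)
                / entry.precursor_mz * 1e6,
                spectral_score=spectral_similarity(feature.ms2, ref, params),
                rt_score=rt_similarity(feature.rt, entry.predicted_rt, params),
                accepted=False,
            )
            scored.append(ident)
        kept = [c for c in scored if c.spectral_score > params.spectral_threshold]
        if kept:
            best = min(
                kept,
                key=lambda c: (-c.spectral_score, abs(c.mass_error_ppm), c.species_id),
            )
            if best.rt_score > params.rt_threshold:
                best.accepted = True
        out.extend(scored)
    return out


def accepted(identifications: list[Identification]) -> list[Identification]:
    return [i for i in identifications if i.accepted]


def write_identifications(identifications: list[Identification], path) -> None:
    """Write the identification audit TSV."""
    import pandas as pd

    rows = [
        {
            "feature_id": i.feature_id,
            "species_id": i.library_key[0],
            "mode": i.library_key[1],
            "adduct": i.library_key[2],
            "mass_error_ppm": repr(i.mass_error_ppm),
            "spectral_score": repr(i.spectral_score),
            "rt_score": repr(i.rt_score),
            "accepted": int(i.accepted),
        }
        for i in identifications
    ]
    pd.DataFrame(
        rows,
        columns=["feature_id", "species_id", "mode", "adduct", "mass_error_ppm",
                 "spectral_score", "rt_score", "accepted"],
    ).to_csv(path, sep="\t", index=False)


def read_identifications(path) -> list[Identification]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"feature_id": str, "species_id": str},
                     float_precision="round_trip")
    return [
        Identification(
            feature_id=r.feature_id,
            library_key=(r.species_id, r.mode, r.adduct),
            mass_error_ppm=float(r.mass_error_ppm),
            spectral_score=float(r.spectral_score),
            rt_score=float(r.rt_score),
            accepted=bool(r.accepted),
        )
        for r in df.itertuples(index=False)
    ]
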