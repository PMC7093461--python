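"""Ground-truth simulator for the whole pipeline.

Generates everything the pipeline consumes — an in-silico spectral library,
a two-group (lipid-raft vs non-raft) feature-table experiment with spiked
deuterated internal standards, calibration-curve levels, and residue-resolved
NMR peak tables — with the generating truth retained, so every stage can be
checked against known answers.

The default experiment emulates the study conditions: 3 biological replicates
per membrane fraction; sphingomyelin and cholesterol enriched in the raft
fraction and acidic phospholipids (PS/PI/PG) in the non-raft fraction;
shorter acyl tails in the raft and more unsaturation in the non-raft;
log-normal peak-area and fragment-intensity noise; Gaussian RT jitter;
decoy library entries and unknown (off-library) features.

All randomness flows from a single root seed through fixed-offset child
streams, so e.g. noise levels can change without changing the truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .features import (
    Feature,
    NONRAFT_SPIKES,
    RAFT_SPIKES,
    SampleMeta,
    Spectrum,
)
from .library import (
    FragmentPeak,
    LibraryEntry,
    LipidSpecies,
    SpectralLibrary,
    SUBCLASSES,
    make_species,
    precursor_mz,
)
from .nmr import PeakTable

# deuteration shifts: one 2H-for-1H substitution adds 1.006277 Da
D_SHIFT = 2.014102 - 1.007825
D7 = 7 * D_SHIFT
D9 = 9 * D_SHIFT

# subclass -> (ion mode, adduct) used for library entries
SUBCLASS_IONIZATION = {
    "PC": ("positive", "[M+H]+"),
    "SM": ("positive", "[M+H]+"),
    "LPC": ("positive", "[M+H]+"),
    "Cer": ("positive", "[M+H]+"),
    "TG": ("positive", "[M+NH4]+"),
    "Chol": ("positive", "[M+H]+"),
    "PE": ("negative", "[M-H]-"),
    "PS": ("negative", "[M-H]-"),
    "PI": ("negative", "[M-H]-"),
    "PG": ("negative", "[M-H]-"),
    "PA": ("negative", "[M-H]-"),
    "LPE": ("negative", "[M-H]-"),
}

# subclass-diagnostic fragment m/z (e.g. the phosphocholine head group ion
# for PC) — constant within a subclass, distinct between subclasses
_DIAGNOSTIC_MZ = {
    "PC": 184.0733, "PE": 196.0380, "PS": 152.9958, "PI": 241.0119,
    "PG": 152.9958 + 20.0, "PA": 152.9958 + 6.0, "Cer": 264.2686,
    "SM": 184.0733, "LPC": 104.1070, "LPE": 140.0118, "TG": 173.0000,
    "Chol": 369.3516,
}

# elution-model coefficients: RT = offset + c1*carbons - c2*double_bonds
RT_CARBON_COEF = 0.15  # min per acyl carbon
RT_DB_COEF = 0.35  # min per double bond
_RT_OFFSET = {
    "LPC": 0.8, "LPE": 1.0, "PG": 1.6, "PI": 1.8, "PS": 2.0, "PA": 2.2,
    "PE": 2.6, "PC": 3.0, "SM": 3.4, "Cer": 6.0, "Chol": 12.0, "TG": 9.0,
}

# non-raft baseline mixture: pmol per subclass (divided among its species);
# raft samples multiply these by the subclass effects.  Proportions mirror a
# phospholipid/cholesterol-dominated vesicle membrane with sphingomyelin at
# 0.12 mol% in the non-raft fraction.
_BASE_POOL_PMOL = {
    "PC": 450.0, "PE": 250.0, "Chol": 150.0, "PS": 60.0, "PI": 35.0,
    "PG": 10.0, "PA": 7.0, "Cer": 5.0, "SM": 1.2, "LPC": 3.0,
    "LPE": 3.0, "TG": 25.0,
}

# per-subclass detector response (area units per microgram)
_RESPONSE = {
    "PC": 1.2e4, "PE": 1.0e4, "PS": 8.0e3, "PI": 7.0e3, "PG": 9.0e3,
    "PA": 6.0e3, "Cer": 1.5e4, "SM": 1.3e4, "LPC": 1.1e4, "LPE": 9.5e3,
    "TG": 2.0e4, "Chol": 5.0e3,
}

# raft / non-raft mol% ratio per subclass: sphingomyelin (x6.25, the 0.75 vs
# 0.12 mol% contrast), cholesterol and ceramide enriched in the raft; acidic
# phospholipids (PS/PI/PG, PA mildly) depleted.  The table is mole-balanced
# against _BASE_POOL_PMOL (sum of (effect-1)*pool = 0) so both groups carry
# the same total lipid pool and every configured effect equals the generated
# mol% ratio exactly at zero noise.
DEFAULT_SUBCLASS_EFFECTS = {
    "SM": 6.25, "Chol": 2.0, "Cer": 1.5, "PC": 0.96, "PE": 0.7,
    "PS": 0.4, "PI": 0.4, "PG": 0.4, "PA": 0.8,
    "LPC": 0.8, "LPE": 0.8, "TG": 0.992,
}


@dataclass
class SimulationConfig:
    seed: int = 0
    n_species_per_subclass: int = 5
    replicates_per_group: int = 3
    subclass_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBCLASS_EFFECTS)
    )
    chain_effect: float = 0.1  # log-amount tilt per carbon favoring short tails in raft
    saturation_effect: float = 0.4  # log-amount tilt per double bond (non-raft keeps more)
    area_noise_sigma: float = 0.1  # log-normal sigma on peak areas
    rt_jitter_sd: float = 0.05  # minutes
    fragment_noise_sigma: float = 0.2  # log-normal sigma on fragment intensities
    contaminant_peaks: int = 2  # spurious peaks added per MS/MS spectrum when noisy
    n_decoy_library: int = 10
    n_unknown_features: int = 10
    dropout_rate: float = 0.0
    protein_amount_ug: float = 50.0

    def __post_init__(self):
        if self.replicates_per_group < 1:
            raise ValueError("need >= 1 replicate per group")
        for name in ("area_noise_sigma", "rt_jitter_sd", "fragment_noise_sigma",
                     "dropout_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def rng(self, stream: int) -> np.random.Generator:
        """Child generator for a fixed-offset stream of the root seed."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))

    def to_dict(self) -> dict:
        return asdict(self)


# child-stream offsets (fixed so truth is stable when noise settings change)
_STREAM_LIBRARY = 1
_STREAM_AMOUNTS = 2
_STREAM_AREA_NOISE = 3
_STREAM_RT_NOISE = 4
_STREAM_FRAGMENT_NOISE = 5
_STREAM_UNKNOWNS = 6
_STREAM_DROPOUT = 7
_STREAM_NMR = 8
_STREAM_CALIBRATION = 9


@dataclass
class GroundTruth:
    species_amounts: dict[str, dict[str, float]] = field(default_factory=dict)
    feature_truth: dict[str, str] = field(default_factory=dict)
    library_flags: dict[str, str] = field(default_factory=dict)  # real | decoy | is
    nmr_attenuation: dict[str, dict[int, float]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# library generation

_CARBON_GRID = {
    "default": (30, 42), "LPC": (14, 22), "LPE": (14, 22), "TG": (46, 56),
    "Cer": (30, 42), "SM": (30, 42),
}


def _grid_for(subclass: str) -> tuple[int, int]:
    return _CARBON_GRID.get(subclass, _CARBON_GRID["default"])


def _fragments_for(
    species: LipidSpecies, prec_mz: float, rng: np.random.Generator
) -> list[FragmentPeak]:
    """Diagnostic ion + neutral-loss ion + two acyl-chain ions.

    Fragment m/z are kept > 2x the matching tolerance apart so a noise-free
    spectrum self-matches perfectly.
    """
    c = species.total_carbons
    db = species.total_double_bonds
    c1, c2 = c // 2, c - c // 2
    db1, db2 = db // 2, db - db // 2
    mzs = [
        _DIAGNOSTIC_MZ[species.subclass],
        prec_mz - 59.0 - (species.label_mass_shift * 0.5),
        227.2006 + 14.01565 * (c1 - 16) - 2.01565 * db1,
        255.2319 + 14.01565 * (c2 - 16) - 2.01565 * db2 + 0.11,
    ]
    # seeded intensity simplex draw, scaled to a 100-unit base peak
    raw = rng.dirichlet(np.ones(len(mzs))) + 0.05
    intensities = raw / raw.max() * 100.0
    peaks = []
    seen: list[float] = []
    for mz, inten in zip(mzs, intensities):
        mz = max(mz, 50.0)
        while any(abs(mz - s) < 0.05 for s in seen):
            mz += 0.06
        seen.append(mz)
        peaks.append(FragmentPeak(round(mz, 4), float(round(inten, 3))))
    return sorted(peaks, key=lambda p: p.mz)


def _make_entry(species: LipidSpecies, rng: np.random.Generator) -> LibraryEntry:
    mode, adduct = SUBCLASS_IONIZATION[species.subclass]
    mz = precursor_mz(species.monoisotopic_mass, adduct)
    rt = _RT_OFFSET[species.subclass] + RT_CARBON_COEF * species.total_carbons \
        - RT_DB_COEF * species.total_double_bonds
    if species.subclass == "Chol":
        rt = _RT_OFFSET["Chol"]
    return LibraryEntry(
        species_id=species.species_id,
        mode=mode,
        adduct=adduct,
        precursor_mz=mz,
        fragments=_fragments_for(species, mz, rng),
        predicted_rt=max(rt, 0.5),
    )


def generate_library(config: SimulationConfig) -> tuple[SpectralLibrary, GroundTruth]:
    """Library spanning the 12 subclasses + the IS panel + decoy entries."""
    rng = config.rng(_STREAM_LIBRARY)
    species: dict[str, LipidSpecies] = {}
    entries: list[LibraryEntry] = []
    truth = GroundTruth()

    def add(sp: LipidSpecies, flag: str) -> None:
        species[sp.species_id] = sp
        entries.append(_make_entry(sp, rng))
        truth.library_flags[sp.species_id] = flag

    compositions: dict[str, set[tuple[int, int]]] = {sc: set() for sc in SUBCLASSES}
    for subclass in SUBCLASSES:
        if subclass == "Chol":
            if config.n_species_per_subclass > 0:
                add(make_species("Chol", "Chol", 27, 1), "real")
                compositions["Chol"].add((27, 1))
            continue
        lo, hi = _grid_for(subclass)
        for _ in range(config.n_species_per_subclass):
            for _attempt in range(200):
                c = int(rng.integers(lo, hi + 1)) // 2 * 2  # even total carbons
                db = int(rng.integers(0, 7 if subclass not in ("SM", "Cer") else 3))
                if (c, db) not in compositions[subclass]:
                    break
            else:
                continue
            compositions[subclass].add((c, db))
            add(make_species(f"{subclass}({c}:{db})", subclass, c, db), "real")

    # deuterated internal standards, one per subclass
    for subclass in SUBCLASSES:
        shift = D9 if subclass == "SM" else D7
        if subclass == "Chol":
            c, db = 27, 1
        else:
            lo, _hi = _grid_for(subclass)
            c, db = lo + 3 - (lo + 3) % 2 + 1, 1  # odd-carbon composition, IS-like
            while (c, db) in compositions[subclass]:
                c += 2
        sp = make_species(
            f"IS-{subclass}-d{9 if subclass == 'SM' else 7}", subclass, c, db,
            is_internal_standard=True, label_mass_shift=shift,
        )
        compositions[subclass].add((c, db))
        add(sp, "is")

    # decoys: compositions never generated in samples
    decoy_subclasses = [sc for sc in SUBCLASSES if sc != "Chol"]
    made = 0
    attempt = 0
    while made < config.n_decoy_library and attempt < 1000:
        attempt += 1
        subclass = decoy_subclasses[int(rng.integers(len(decoy_subclasses)))]
        lo, hi = _grid_for(subclass)
        c = int(rng.integers(lo, hi + 1)) // 2 * 2 + 1  # odd carbons: off the real grid
        db = int(rng.integers(0, 7))
        if (c, db) in compositions[subclass]:
            continue
        compositions[subclass].add((c, db))
        add(make_species(f"DECOY-{subclass}({c}:{db})", subclass, c, db), "decoy")
        made += 1

    return SpectralLibrary(entries=entries, species=species), truth


# ---------------------------------------------------------------------------
# experiment generation

def generate_experiment(
    library: SpectralLibrary,
    truth: GroundTruth,
    config: SimulationConfig,
) -> tuple[list[Feature], list[SampleMeta], GroundTruth]:
    """Two-group feature tables with MS/MS spectra and IS spikes.

    True per-species amounts come from a seeded log-normal base mixture; raft
    samples multiply each subclass by its configured effect and tilt species
    weights toward shorter, more saturated tails; each sample is then
    rescaled to a fixed total lipid pool so a configured subclass effect
    equals the generated mol% ratio exactly at zero noise.
    """
    rng_amounts = config.rng(_STREAM_AMOUNTS)
    rng_area = config.rng(_STREAM_AREA_NOISE)
    rng_rt = config.rng(_STREAM_RT_NOISE)
    rng_frag = config.rng(_STREAM_FRAGMENT_NOISE)
    rng_unknown = config.rng(_STREAM_UNKNOWNS)
    rng_drop = config.rng(_STREAM_DROPOUT)

    entries_by_species = {e.species_id: e for e in library.entries}
    real_species = [
        library.species[sid] for sid, flag in truth.library_flags.items()
        if flag == "real"
    ]

    # base (non-raft) amounts per species: subclass pool split with a seeded
    # log-normal weight per species
    base_amounts: dict[str, float] = {}
    for subclass in SUBCLASSES:
        members = [sp for sp in real_species if sp.subclass == subclass]
        if not members:
            continue
        weights = np.exp(rng_amounts.normal(0.0, 0.4, size=len(members)))
        weights /= weights.sum()
        for sp, w in zip(members, weights):
            base_amounts[sp.species_id] = _BASE_POOL_PMOL[subclass] * float(w)
    pool_total = sum(base_amounts.values())

    # per-group species multipliers: subclass effect x chain/saturation tilt
    mean_c = float(np.mean([sp.total_carbons for sp in real_species]))
    mean_db = float(np.mean([sp.total_double_bonds for sp in real_species]))

    def group_amounts(group: str) -> dict[str, float]:
        if group == "nonraft":
            return dict(base_amounts)
        amounts = {}
        # chain/saturation tilt redistributes species *within* a subclass
        # (renormalized to the subclass total) so each subclass's mol% ratio
        # stays exactly its configured effect
        for subclass in SUBCLASSES:
            members = [sp for sp in real_species if sp.subclass == subclass]
            if not members:
                continue
            sub_total = sum(base_amounts[sp.species_id] for sp in members)
            tilted = {
                sp.species_id: base_amounts[sp.species_id]
                * math.exp(
                    -config.chain_effect * (sp.total_carbons - mean_c)
                    - config.saturation_effect * (sp.total_double_bonds - mean_db)
                )
                for sp in members
            }
            tilt_total = sum(tilted.values())
            effect = config.subclass_effects.get(subclass, 1.0)
            for sid, a in tilted.items():
                amounts[sid] = a / tilt_total * sub_total * effect
        # rescale to the common pool so effects are exact mol% ratios
        scale = pool_total / sum(amounts.values())
        return {sid: a * scale for sid, a in amounts.items()}

    features: list[Feature] = []
    samples: list[SampleMeta] = []
    for group in ("raft", "nonraft"):
        amounts = group_amounts(group)
        spikes = RAFT_SPIKES if group == "raft" else NONRAFT_SPIKES
        for rep in range(1, config.replicates_per_group + 1):
            sample_id = f"{group}_{rep}"
            samples.append(
                SampleMeta(
                    sample_id=sample_id,
                    group=group,
                    protein_amount=config.protein_amount_ug,
                    is_spikes=dict(spikes),
                )
            )
            truth.species_amounts[sample_id] = dict(amounts)
            k = 0
            for sp in real_species:
                entry = entries_by_species[sp.species_id]
                pmol = amounts[sp.species_id]
                if config.dropout_rate > 0 and rng_drop.random() < config.dropout_rate:
                    continue
                amount_ug = pmol * sp.average_mw * 1e-6
                area = amount_ug * _RESPONSE[sp.subclass]
                if config.area_noise_sigma > 0:
                    area *= math.exp(rng_area.normal(0.0, config.area_noise_sigma))
                k += 1
                fid = f"{sample_id}_F{k:04d}"
                features.append(
                    _feature_from_entry(fid, sample_id, entry, area, config,
                                        rng_rt, rng_frag)
                )
                truth.feature_truth[fid] = sp.species_id
            # spiked internal standards (never dropped)
            for subclass, spiked_ug in spikes.items():
                is_sp = _is_species(library, subclass)
                if is_sp is None:
                    continue
                entry = entries_by_species[is_sp.species_id]
                area = spiked_ug * _RESPONSE[subclass]
                if config.area_noise_sigma > 0:
                    area *= math.exp(rng_area.normal(0.0, config.area_noise_sigma))
                k += 1
                fid = f"{sample_id}_F{k:04d}"
                features.append(
                    _feature_from_entry(fid, sample_id, entry, area, config,
                                        rng_rt, rng_frag)
                )
                truth.feature_truth[fid] = is_sp.species_id

    # unknown features: m/z far (>5x the usual ppm tolerance) from every entry
    lib_mz = np.array([e.precursor_mz for e in library.entries])
    made = 0
    while made < config.n_unknown_features:
        mz = float(rng_unknown.uniform(350.0, 950.0))
        if np.min(np.abs(lib_mz - mz)) / mz * 1e6 < 50.0:
            continue
        sample = samples[made % len(samples)]
        fid = f"{sample.sample_id}_U{made:03d}"
        peaks = [
            FragmentPeak(float(rng_unknown.uniform(80.0, mz)),
                         float(rng_unknown.uniform(5.0, 100.0)))
            for _ in range(3)
        ]
        features.append(
            Feature(
                feature_id=fid,
                sample_id=sample.sample_id,
                mz=mz,
                rt=float(rng_unknown.uniform(1.0, 20.0)),
                area=float(rng_unknown.lognormal(8.0, 1.0)),
                ms2=Spectrum(peaks=list(peaks), mode="positive", precursor_mz=mz),
            )
        )
        truth.feature_truth[fid] = "unknown"
        made += 1

    return features, samples, truth


def _is_species(library: SpectralLibrary, subclass: str) -> LipidSpecies | None:
    for sp in library.species.values():
        if sp.is_internal_standard and sp.subclass == subclass:
            return sp
    return None


def _feature_from_entry(
    feature_id: str,
    sample_id: str,
    entry: LibraryEntry,
    area: float,
    config: SimulationConfig,
    rng_rt: np.random.Generator,
    rng_frag: np.random.Generator,
) -> Feature:
    rt = entry.predicted_rt
    if config.rt_jitter_sd > 0:
        rt += float(rng_rt.normal(0.0, config.rt_jitter_sd))
    rt = max(rt, 0.0)
    peaks = []
    for p in entry.fragments:
        inten = p.intensity
        if config.fragment_noise_sigma > 0:
            inten *= math.exp(rng_frag.normal(0.0, config.fragment_noise_sigma))
        peaks.append(FragmentPeak(p.mz, inten))
    if config.fragment_noise_sigma > 0 and config.contaminant_peaks > 0:
        for _ in range(config.contaminant_peaks):
            peaks.append(
                FragmentPeak(
                    float(rng_frag.uniform(60.0, entry.precursor_mz)),
                    float(rng_frag.uniform(1.0, 15.0)),
                )
            )
    return Feature(
        feature_id=feature_id,
        sample_id=sample_id,
        mz=entry.precursor_mz,
        rt=rt,
        area=area,
        ms2=Spectrum(peaks=peaks, mode=entry.mode, precursor_mz=entry.precursor_mz),
    )


# ---------------------------------------------------------------------------
# calibration-curve levels

DEFAULT_CALIBRATION_LEVELS = (0.5, 1.0, 5.0, 20.0, 50.0, 100.0, 200.0)  # ug/mL


def generate_calibration(
    true_slope: float,
    true_intercept: float,
    levels: tuple[float, ...] = DEFAULT_CALIBRATION_LEVELS,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> list[tuple[float, float]]:
    """Response-ratio levels on a known line, with optional Gaussian noise."""
    if rng is None:
        rng = np.random.default_rng(0)
    out = []
    for conc in levels:
        rr = true_slope * conc + true_intercept
        if noise_sd > 0:
            rr += float(rng.normal(0.0, noise_sd))
        out.append((conc, rr))
    return out


# ---------------------------------------------------------------------------
# NMR profiles

#: residues unassignable in the construct: a plausible synthetic set of eight
#: N-terminal prolines plus T27 and S61 (the real assignment gaps are not
#: reproduced; only their existence and rough geography matter downstream)
SYNTHETIC_MISSING_RESIDUES = frozenset({9, 10, 13, 19, 20, 23, 24, 25, 27, 61})


@dataclass
class NmrSimConfig:
    seed: int = 0
    n_residues: int = 96
    reference_residue: int = 5
    snare_region: tuple[int, int] = (35, 78)  # half-open, intermediate attenuation
    jmd_region: tuple[int, int] = (78, 97)  # complete signal loss in cells
    nt_end: int = 28  # proline-rich N-terminus: no attenuation
    snare_attenuation: float = 0.5
    linker_attenuation: float = 0.8  # residues between NT and the SNARE core
    chol_up_effect: float = 0.3  # +30% SNARE-motif Y in cholesterol-up cells
    chol_down_effect: float = -0.3
    noise_sigma: float = 0.0
    missing_residues: frozenset[int] = SYNTHETIC_MISSING_RESIDUES


def generate_nmr_profiles(
    config: NmrSimConfig,
) -> tuple[dict[str, PeakTable], GroundTruth]:
    """Peak tables for {solution, cell, chol_up, chol_down} plus the truth.

    Solution intensities are high and flexible at the N-terminus, tapering
    toward the C-terminus; cellular conditions multiply them by a region-wise
    attenuation profile (N-terminus ~1, SNARE motif intermediate, residues in
    the JMD window 0 = disappeared); cholesterol up/down scale the
    SNARE-motif attenuation by the configured effects.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _STREAM_NMR]))
    truth = GroundTruth()

    def attenuation(condition: str, residue: int) -> float:
        s0, s1 = config.snare_region
        j0, j1 = config.jmd_region
        if j0 <= residue < j1:
            return 0.0
        if s0 <= residue < s1:
            a = config.snare_attenuation
            if condition == "chol_up":
                a *= 1.0 + config.chol_up_effect
            elif condition == "chol_down":
                a *= 1.0 + config.chol_down_effect
            return a
        if residue < config.nt_end:
            return 1.0
        return config.linker_attenuation

    solution: dict[int, float | None] = {}
    for residue in range(1, config.n_residues + 1):
        if residue in config.missing_residues:
            solution[residue] = None
        else:
            taper = 1.0 - 0.4 * max(residue - config.nt_end, 0) / (
                config.n_residues - config.nt_end
            )
            solution[residue] = 100.0 * taper

    tables = {"solution": PeakTable("solution", dict(solution), config.n_residues)}
    for condition in ("cell", "chol_up", "chol_down"):
        intensities: dict[int, float | None] = {}
        truth.nmr_attenuation[condition] = {}
        for residue, i0 in solution.items():
            if i0 is None:
                intensities[residue] = None
                continue
            a = attenuation(condition, residue)
            value = i0 * a
            if config.noise_sigma > 0 and value > 0:
                value *= math.exp(rng.normal(0.0, config.noise_sigma))
            intensities[residue] = value
            truth.nmr_attenuation[condition][residue] = a
        tables[condition] = PeakTable(condition, intensities, config.n_residues)
    return tables, truth
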