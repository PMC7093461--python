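"""In-silico lipid spectral library: data model, mass model, and MSP-like I/O.

The identification stage searches a library of lipid molecular species, each
carried as one or more ionized forms (adducts) with a fragment spectrum and a
predicted retention time.  Species masses follow the homologous-series
structure of glycerophospholipid chemistry: a per-subclass base mass plus
14.01565 Da per acyl carbon (CH2) and -2.01565 Da per C=C (loss of H2).
Cholesterol is a fixed-composition sterol (27 carbons) and is special-cased.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

from .errors import ConfigurationError, ParseError, ValidationError

PROTON_MASS = 1.007276  # Da, charge carrier for singly charged ions
CH2 = 14.01565  # Da per additional acyl carbon
H2 = 2.01565  # Da removed per additional double bond

SUBCLASSES = ("PC", "PE", "PS", "PI", "PG", "PA", "Cer", "SM", "LPC", "LPE", "TG", "Chol")
GLYCEROPHOSPHOLIPIDS = ("PC", "PE", "PS", "PI", "PG", "PA")

#: monoisotopic mass of cholesterol (C27H46O, fixed composition)
CHOLESTEROL_MASS = 386.3549
CHOLESTEROL_CARBONS = 27

# Base mass of each homologous series, anchored at a reference species
# (e.g. PC 34:1 = 759.5778 Da) so that
#   mass = base + CH2 * total_carbons - H2 * total_double_bonds.
_SUBCLASS_BASE = {
    "PC": 759.5778 - 34 * CH2 + 1 * H2,
    "PE": 717.5309 - 34 * CH2 + 1 * H2,
    "PS": 761.5207 - 34 * CH2 + 1 * H2,
    "PI": 836.5415 - 34 * CH2 + 1 * H2,
    "PG": 748.5254 - 34 * CH2 + 1 * H2,
    "PA": 674.4886 - 34 * CH2 + 1 * H2,
    "SM": 702.5676 - 34 * CH2 + 1 * H2,
    "Cer": 537.5121 - 34 * CH2 + 1 * H2,
    "LPC": 495.3325 - 16 * CH2,
    "LPE": 453.2855 - 16 * CH2,
    "TG": 858.7676 - 52 * CH2 + 2 * H2,
}

# Adduct name -> (ion mode, m/z shift from the neutral monoisotopic mass).
# Singly charged ions only.
ADDUCTS = {
    "[M+H]+": ("positive", +PROTON_MASS),
    "[M+NH4]+": ("positive", +18.033823),
    "[M-H]-": ("negative", -PROTON_MASS),
    "[M+HCOO]-": ("negative", +44.998201),
}


def _normalize_adduct(name: str) -> str:
    # accept the typographic minus sign
    return name.replace("−", "-")


def precursor_mz(monoisotopic_mass: float, adduct: str) -> float:
    """m/z of the singly charged adduct ion of a neutral species.

    Raises ConfigurationError for adducts absent from the configured table.
    """
    adduct = _normalize_adduct(adduct)
    if adduct not in ADDUCTS:
        raise ConfigurationError(
            f"unknown adduct {adduct!r}; configured adducts: {sorted(ADDUCTS)}"
        )
    return monoisotopic_mass + ADDUCTS[adduct][1]


def adduct_mode(adduct: str) -> str:
    adduct = _normalize_adduct(adduct)
    if adduct not in ADDUCTS:
        raise ConfigurationError(f"unknown adduct {adduct!r}")
    return ADDUCTS[adduct][0]


def species_mass(subclass: str, total_carbons: int, total_double_bonds: int) -> float:
    """Monoisotopic mass of an unlabeled species from the homologous-series model."""
    if subclass == "Chol":
        if total_carbons != CHOLESTEROL_CARBONS:
            raise ValidationError("cholesterol has a fixed 27-carbon skeleton")
        return CHOLESTEROL_MASS
    if subclass not in _SUBCLASS_BASE:
        raise ValidationError(f"unknown subclass {subclass!r}")
    return _SUBCLASS_BASE[subclass] + CH2 * total_carbons - H2 * total_double_bonds


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid molecular species at the subclass + total-composition level.

    ``label_mass_shift`` carries the deuteration shift of internal standards
    (already included in ``monoisotopic_mass``); 0 for unlabeled analytes.
    """

    species_id: str
    subclass: str
    total_carbons: int
    total_double_bonds: int
    monoisotopic_mass: float
    average_mw: float
    is_internal_standard: bool = False
    label_mass_shift: float = 0.0

    def __post_init__(self):
        if self.subclass not in SUBCLASSES:
            raise ValidationError(f"unknown subclass {self.subclass!r}")
        if self.total_carbons < 0 or self.total_double_bonds < 0:
            raise ValidationError("carbon and double-bond counts must be >= 0")
        if self.monoisotopic_mass <= 0 or self.average_mw <= 0:
            raise ValidationError("masses must be positive")
        if self.subclass == "Chol" and self.total_carbons != CHOLESTEROL_CARBONS:
            raise ValidationError("cholesterol species must have 27 carbons")


def make_species(
    species_id: str,
    subclass: str,
    total_carbons: int,
    total_double_bonds: int,
    *,
    is_internal_standard: bool = False,
    label_mass_shift: float = 0.0,
    average_mw: float | None = None,
) -> LipidSpecies:
    """Construct a species with masses from the built-in homologous-series model.

    average_mw defaults to monoisotopic_mass * 1.0007 (overridable), adequate
    for the microgram-to-picomole conversion the quantification stage needs.
    """
    mono = species_mass(subclass, total_carbons, total_double_bonds) + label_mass_shift
    if average_mw is None:
        average_mw = mono * 1.0007
    return LipidSpecies(
        species_id=species_id,
        subclass=subclass,
        total_carbons=total_carbons,
        total_double_bonds=total_double_bonds,
        monoisotopic_mass=mono,
        average_mw=average_mw,
        is_internal_standard=is_internal_standard,
        label_mass_shift=label_mass_shift,
    )


@dataclass(frozen=True)
class FragmentPeak:
    mz: float
    intensity: float

    def __post_init__(self):
        if self.mz <= 0:
            raise ValidationError("fragment m/z must be > 0")
        if self.intensity < 0:
            raise ValidationError("fragment intensity must be >= 0")


@dataclass
class LibraryEntry:
    """One ionized form of a species: adduct, precursor m/z, spectrum, predicted RT."""

    species_id: str
    mode: str
    adduct: str
    precursor_mz: float
    fragments: list[FragmentPeak]
    predicted_rt: float

    def __post_init__(self):
        if self.mode not in ("positive", "negative"):
            raise ValidationError(f"mode must be positive/negative, got {self.mode!r}")
        if self.precursor_mz <= 0:
            raise ValidationError("precursor m/z must be > 0")
        if not self.fragments:
            raise ValidationError("library entry needs at least one fragment")
        if self.predicted_rt < 0:
            raise ValidationError("predicted RT must be >= 0")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.species_id, self.mode, self.adduct)


@dataclass
class SpectralLibrary:
    entries: list[LibraryEntry] = field(default_factory=list)
    species: dict[str, LipidSpecies] = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        seen = set()
        for e in self.entries:
            if e.species_id not in self.species:
                raise ValidationError(f"entry references unknown species {e.species_id!r}")
            if e.key in seen:
                raise ValidationError(f"duplicate library entry {e.key}")
            seen.add(e.key)

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# MSP-like text format
#
# Records separated by blank lines.  Header lines KEY: value, then NumPeaks
# peak lines "mz<TAB>intensity".  Species-level fields ride along on every
# record so a library round-trips losslessly.

_FMT = "{!r}".format  # shortest exact decimal repr -> lossless float round-trip


def _write_record(out: io.TextIOBase, entry: LibraryEntry, sp: LipidSpecies) -> None:
    out.write(f"NAME: {sp.species_id}\n")
    out.write(f"SUBCLASS: {sp.subclass}\n")
    out.write(f"MODE: {entry.mode}\n")
    out.write(f"ADDUCT: {entry.adduct}\n")
    out.write(f"PRECURSORMZ: {_FMT(entry.precursor_mz)}\n")
    out.write(f"PREDICTED_RT: {_FMT(entry.predicted_rt)}\n")
    out.write(f"MW: {_FMT(sp.average_mw)}\n")
    out.write(f"MONOISOTOPIC: {_FMT(sp.monoisotopic_mass)}\n")
    out.write(f"CARBONS: {sp.total_carbons}\n")
    out.write(f"DOUBLEBONDS: {sp.total_double_bonds}\n")
    out.write(f"INTERNAL_STANDARD: {int(sp.is_internal_standard)}\n")
    out.write(f"LABEL_SHIFT: {_FMT(sp.label_mass_shift)}\n")
    out.write(f"NumPeaks: {len(entry.fragments)}\n")
    for p in entry.fragments:
        out.write(f"{_FMT(p.mz)}\t{_FMT(p.intensity)}\n")


def write_library(library: SpectralLibrary, path) -> None:
    """Write a library in the MSP-like dialect; parses back to an equal library."""
    library.validate()
    with open(path, "w", encoding="utf-8") as out:
        for i, entry in enumerate(library.entries):
            if i:
                out.write("\n")
            _write_record(out, entry, library.species[entry.species_id])


def read_library(path) -> SpectralLibrary:
    """Parse the MSP-like dialect written by :func:`write_library`.

    Malformed records raise ParseError with the offending line number;
    duplicate (species, mode, adduct) keys raise ValidationError.
    """
    entries: list[LibraryEntry] = []
    species: dict[str, LipidSpecies] = {}
    header: dict[str, str] = {}
    peaks: list[FragmentPeak] = []
    npeaks_line = 0

    def flush(lineno: int) -> None:
        nonlocal header, peaks
        if not header and not peaks:
            return
        required = ("NAME", "SUBCLASS", "MODE", "ADDUCT", "PRECURSORMZ",
                    "PREDICTED_RT", "MW", "NumPeaks")
        for key in required:
            if key not in header:
                raise ParseError(f"record missing {key}", lineno)
        n = int(header["NumPeaks"])
        if len(peaks) != n:
            raise ParseError(
                f"NumPeaks says {n} but record has {len(peaks)} peak lines", lineno
            )
        sid = header["NAME"]
        try:
            sp = LipidSpecies(
                species_id=sid,
                subclass=header["SUBCLASS"],
                total_carbons=int(header.get("CARBONS", 0)),
                total_double_bonds=int(header.get("DOUBLEBONDS", 0)),
                monoisotopic_mass=float(header.get("MONOISOTOPIC", header["PRECURSORMZ"])),
                average_mw=float(header["MW"]),
                is_internal_standard=bool(int(header.get("INTERNAL_STANDARD", "0"))),
                label_mass_shift=float(header.get("LABEL_SHIFT", "0")),
            )
        except (ValueError, ValidationError) as exc:
            raise ParseError(str(exc), lineno) from exc
        if sid in species and species[sid] != sp:
            raise ValidationError(f"species {sid!r} redefined with different fields")
        species[sid] = sp
        try:
            entries.append(
                LibraryEntry(
                    species_id=sid,
                    mode=header["MODE"],
                    adduct=header["ADDUCT"],
                    precursor_mz=float(header["PRECURSORMZ"]),
                    fragments=peaks,
                    predicted_rt=float(header["PREDICTED_RT"]),
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ParseError(str(exc), lineno) from exc
        header, peaks = {}, []

    with open(path, encoding="utf-8") as fh:
        lineno = 0
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                flush(lineno)
                continue
            if ":" in line and not peaks and not _looks_like_peak(line):
                key, _, value = line.partition(":")
                header[key.strip()] = value.strip()
            else:
                fields = line.split("\t")
                if len(fields) != 2:
                    raise ParseError(f"expected 'mz<TAB>intensity', got {line!r}", lineno)
                try:
                    peaks.append(FragmentPeak(float(fields[0]), float(fields[1])))
                except (ValueError, ValidationError) as exc:
                    raise ParseError(str(exc), lineno) from exc
        flush(lineno)

    lib = SpectralLibrary(entries=entries, species=species)
    return lib


def _looks_like_peak(line: str) -> bool:
    fields = line.split("\t")
    if len(fields) != 2:
        return False
    try:
        float(fields[0]), float(fields[1])
        return True
    except ValueError:
        return False
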