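"""Subclass compositions, chain-length/saturation profiles, group comparisons.

mol% is computed on mole amounts: all molecular species of a subclass are
summed per sample and divided by the sample's total lipid moles (x100).  The
per-protein view sums pmol per microgram protein instead.  Group comparisons
use a two-sided two-sample Student's t-test (pooled variance by default,
Welch optional) per subclass on the replicate mol% values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ValidationError
from .library import GLYCEROPHOSPHOLIPIDS, SpectralLibrary
from .quantify import QuantRecord


@dataclass
class CompositionProfile:
    sample_id: str
    subclass_mol_percent: dict[str, float] = field(default_factory=dict)
    subclass_per_protein: dict[str, float] = field(default_factory=dict)


@dataclass
class ChainProfile:
    """Mole-fraction distributions over total carbons and double bonds."""

    sample_id: str
    carbon_fractions: dict[int, float] = field(default_factory=dict)
    double_bond_fractions: dict[int, float] = field(default_factory=dict)

    @property
    def mean_carbons(self) -> float:
        return sum(c * f for c, f in self.carbon_fractions.items())

    @property
    def mean_double_bonds(self) -> float:
        return sum(d * f for d, f in self.double_bond_fractions.items())


@dataclass
class GroupComparison:
    subclass: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t_statistic: float
    p_value: float
    significance_label: str


def _usable(records: list[QuantRecord]) -> list[QuantRecord]:
    return [r for r in records if r.error is None and not math.isnan(r.amount_pmol)]


def subclass_composition(
    quant: list[QuantRecord], library: SpectralLibrary | None = None
) -> list[CompositionProfile]:
    """Per-sample subclass mol% and pmol-per-ug-protein profiles.

    Subclasses quantified anywhere in the data set contribute 0 (not missing)
    to samples where they are absent, keeping denominators comparable.
    """
    records = _usable(quant)
    samples = sorted({r.sample_id for r in records})
    subclasses = sorted({r.subclass for r in records})
    profiles = []
    for sample_id in samples:
        rows = [r for r in records if r.sample_id == sample_id]
        total = sum(r.amount_pmol for r in rows)
        if total <= 0:
            raise ValidationError(f"total lipid amount is 0 in sample {sample_id!r}")
        mol = {sc: 0.0 for sc in subclasses}
        per_protein = {sc: 0.0 for sc in subclasses}
        for r in rows:
            mol[r.subclass] += r.amount_pmol
            per_protein[r.subclass] += r.amount_per_protein
        profiles.append(
            CompositionProfile(
                sample_id=sample_id,
                subclass_mol_percent={sc: v / total * 100.0 for sc, v in mol.items()},
                subclass_per_protein=per_protein,
            )
        )
    return profiles


def chain_profiles(
    quant: list[QuantRecord],
    library: SpectralLibrary,
    subclasses: tuple[str, ...] = GLYCEROPHOSPHOLIPIDS,
) -> list[ChainProfile]:
    """Per-sample mole-fraction histograms over acyl carbons and double bonds.

    Restricted to glycerophospholipids by default, matching how tail length
    and saturation are compared between membrane fractions.
    """
    records = [r for r in _usable(quant) if r.subclass in subclasses]
    profiles = []
    for sample_id in sorted({r.sample_id for r in records}):
        rows = [r for r in records if r.sample_id == sample_id]
        total = sum(r.amount_pmol for r in rows)
        if total <= 0:
            continue
        carbons: dict[int, float] = {}
        dbs: dict[int, float] = {}
        for r in rows:
            sp = library.species[r.species_id]
            frac = r.amount_pmol / total
            carbons[sp.total_carbons] = carbons.get(sp.total_carbons, 0.0) + frac
            dbs[sp.total_double_bonds] = dbs.get(sp.total_double_bonds, 0.0) + frac
        profiles.append(
            ChainProfile(
                sample_id=sample_id,
                carbon_fractions=dict(sorted(carbons.items())),
                double_bond_fractions=dict(sorted(dbs.items())),
            )
        )
    return profiles


def _label(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.05:
        return "*"
    return "n.s."


def compare_groups(
    profiles_a: list[CompositionProfile],
    profiles_b: list[CompositionProfile],
    welch: bool = False,
) -> list[GroupComparison]:
    """Per-subclass Student's t-test on mol% across replicates (two-sided)."""
    if len(profiles_a) < 2 or len(profiles_b) < 2:
        raise ValidationError("need >= 2 replicates per group")
    subclasses = sorted(
        {sc for p in profiles_a + profiles_b for sc in p.subclass_mol_percent}
    )
    out = []
    for sc in subclasses:
        a = np.array([p.subclass_mol_percent.get(sc, 0.0) for p in profiles_a])
        b = np.array([p.subclass_mol_percent.get(sc, 0.0) for p in profiles_b])
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            # degenerate zero-variance case: scipy yields nan; identical
            # means are a perfect null (t=0, p=1), distinct means a certain
            # difference
            if a[0] == b[0]:
                t, p = 0.0, 1.0
            else:
                t = math.inf if a[0] > b[0] else -math.inf
                p = 0.0
        else:
            res = stats.ttest_ind(a, b, equal_var=not welch)
            t, p = float(res.statistic), float(res.pvalue)
        out.append(
            GroupComparison(
                subclass=sc,
                mean_a=float(a.mean()),
                sd_a=float(a.std(ddof=1)),
                mean_b=float(b.mean()),
                sd_b=float(b.std(ddof=1)),
                t_statistic=t,
                p_value=p,
                significance_label=_label(p),
            )
        )
    return out


def write_composition(profiles: list[CompositionProfile], path) -> None:
    import pandas as pd

    rows = []
    for p in profiles:
        for sc in sorted(p.subclass_mol_percent):
            rows.append(
                {
                    "sample_id": p.sample_id,
                    "subclass": sc,
                    "mol_percent": repr(p.subclass_mol_percent[sc]),
                    "pmol_per_ug_protein": repr(p.subclass_per_protein.get(sc, 0.0)),
                }
            )
    pd.DataFrame(
        rows, columns=["sample_id", "subclass", "mol_percent", "pmol_per_ug_protein"]
    ).to_csv(path, sep="\t", index=False)


def write_comparison(comparisons: list[GroupComparison], path,
                     label_a: str = "raft", label_b: str = "nonraft") -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "subclass": c.subclass,
                f"mean_{label_a}": repr(c.mean_a),
                f"sd_{label_a}": repr(c.sd_a),
                f"mean_{label_b}": repr(c.mean_b),
                f"sd_{label_b}": repr(c.sd_b),
                "t": repr(c.t_statistic),
                "p": repr(c.p_value),
                "label": c.significance_label,
            }
            for c in comparisons
        ]
    ).to_csv(path, sep="\t", index=False)
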