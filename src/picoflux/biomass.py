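"""Biomass composition handling.

Measured macromolecular compositions (FAME/lipid, protein, carbohydrate as
% of ash-free dry weight, plus assumed DNA/RNA/chlorophyll fractions)
rarely close a mass balance; they are corrected here in two steps:
component-specific recovery factors first, then a single global scaling so
the total is exactly 100% AFDW.  The corrected composition and the
specific growth rate are then translated into the precursor sink demands
(mmol precursor per gDW) that anchor the flux model, using an editable
monomer table.  Growth rates come from the slope of ln(TOC) against time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BiomassComposition",
    "GrowthRate",
    "CompositionError",
    "correct_composition",
    "precursor_demands",
    "growth_rate_from_toc",
    "load_monomer_table",
    "load_table_compositions",
    "MACROMOLECULES",
]

MACROMOLECULES = ("fame", "protein", "carbohydrate", "dna", "rna", "chla")


class CompositionError(ValueError):
    pass


@dataclass
class BiomassComposition:
    """Mass fractions in % AFDW, closing to 100 +/- 0.1 after correction."""

    fractions: dict[str, float]
    sds: dict[str, float] = field(default_factory=dict)
    strain: str = ""
    light: str = ""
    scaling_factor: float = 1.0

    @property
    def total(self) -> float:
        return float(sum(self.fractions.values()))

    def __getitem__(self, key: str) -> float:
        return self.fractions[key]


@dataclass
class GrowthRate:
    mu: float  # h^-1
    sd: float = 0.0

    def __post_init__(self):
        if self.mu < -1e-12:
            warnings.warn(f"negative growth rate {self.mu:.4f} h^-1 (declining culture?)")


def correct_composition(
    measured: Mapping[str, float],
    assumed: Mapping[str, float] | None = None,
    correction_factors: Mapping[str, float] | None = None,
    strain: str = "",
    light: str = "",
) -> BiomassComposition:
    """Close the biomass mass balance.

    ``measured`` holds experimentally determined fractions (% AFDW);
    ``assumed`` supplies the unmeasured components (DNA, RNA, chlorophyll,
    taken from literature).  Component-specific ``correction_factors``
    (FAME and carbohydrate under-recovery) are applied first, then every
    component is scaled by a common factor so the total is exactly 100.
    The scaling factor is recorded on the result.
    """
    fractions = {k: float(v) for k, v in measured.items()}
    for k, v in (assumed or {}).items():
        if k in fractions:
            raise CompositionError(f"component {k!r} both measured and assumed")
        fractions[k] = float(v)
    for k, v in fractions.items():
        if not 0.0 <= v <= 100.0:
            raise CompositionError(f"fraction {k}={v} outside [0, 100]")
    for k, f in (correction_factors or {}).items():
        if k in fractions:
            fractions[k] *= float(f)
            if fractions[k] < 0:
                raise CompositionError(f"negative fraction for {k!r} after correction")
    total = sum(fractions.values())
    if total <= 0:
        raise CompositionError("total composition is not positive")
    scale = 100.0 / total
    return BiomassComposition(
        fractions={k: v * scale for k, v in fractions.items()},
        strain=strain,
        light=light,
        scaling_factor=scale,
    )


def load_monomer_table(path=None) -> pd.DataFrame:
    """Monomer/precursor stoichiometry table.

    Columns: macromolecule, monomer, monomer_mass (g/mol of residue as it
    sits in the polymer), weight (default mole fraction of the monomer
    within its class), precursor (network species), coef (mmol precursor
    per mmol monomer), carbons (carbons the precursor contributes).
    Values are literature-typical and editable; the default maps onto the
    bundled core network's species names.
    """
    if path is None:
        path = resources.files("picoflux.data") / "monomers_core.csv"
    df = pd.read_csv(path, comment="#")
    required = {"macromolecule", "monomer", "monomer_mass", "weight", "precursor", "coef", "carbons"}
    missing = required - set(df.columns)
    if missing:
        raise CompositionError(f"monomer table missing columns: {sorted(missing)}")
    return df


def precursor_demands(
    comp: BiomassComposition,
    monomer_table: pd.DataFrame,
    aa_profile: Mapping[str, float] | None = None,
) -> dict[str, dict[str, float]]:
    """Precursor demand per macromolecule class, mmol per gDW biomass.

    For each class: grams of class per gDW = fraction/100; the monomer mix
    (mole fractions from ``aa_profile`` for protein, else the table's
    default weights) sets the mean residue mass, hence mmol monomer per
    gram of class; precursor coefficients then distribute that demand over
    network species.  Returns {class: {species: mmol/gDW}} — the layout
    :func:`~picoflux.network.attach_biomass_sink` consumes.  Demands are
    linear in the composition fractions.
    """
    demands: dict[str, dict[str, float]] = {}
    for cls, grp in monomer_table.groupby("macromolecule"):
        frac = comp.fractions.get(cls, 0.0)
        if frac == 0.0:
            continue
        monomers = grp.drop_duplicates("monomer")[["monomer", "monomer_mass", "weight"]]
        weights = dict(zip(monomers.monomer, monomers.weight.astype(float)))
        if cls == "protein" and aa_profile is not None:
            unknown = set(aa_profile) - set(weights)
            if unknown:
                raise CompositionError(f"amino-acid profile names unknown monomers: {sorted(unknown)}")
            weights = {m: float(aa_profile.get(m, 0.0)) for m in weights}
        elif cls == "protein" and aa_profile is None:
            warnings.warn(
                "no amino-acid profile supplied for protein; using the table's "
                "default (even) weights"
            )
        wsum = sum(weights.values())
        if wsum <= 0:
            raise CompositionError(f"monomer weights for {cls!r} sum to zero")
        weights = {m: w / wsum for m, w in weights.items()}
        masses = dict(zip(monomers.monomer, monomers.monomer_mass.astype(float)))
        mean_mass = sum(weights[m] * masses[m] for m in weights)  # g/mol residue
        mmol_monomer_per_g = 1000.0 / mean_mass
        out: dict[str, float] = {}
        for _, row in grp.iterrows():
            w = weights[row.monomer]
            if w == 0.0:
                continue
            out[row.precursor] = out.get(row.precursor, 0.0) + (
                frac / 100.0 * mmol_monomer_per_g * w * float(row.coef)
            )
        if not out and frac > 0:
            raise CompositionError(f"no monomer entry provides precursors for {cls!r}")
        demands[cls] = out
    for cls in comp.fractions:
        if comp.fractions[cls] > 0 and cls not in demands:
            raise CompositionError(f"missing monomer entries for nonzero class {cls!r}")
    return demands


def total_demand(demands: Mapping[str, Mapping[str, float]]) -> dict[str, float]:
    out: dict[str, float] = {}
    for cls in demands:
        for sp, v in demands[cls].items():
            out[sp] = out.get(sp, 0.0) + v
    return out


def biomass_carbon(
    demands: Mapping[str, Mapping[str, float]],
    monomer_table: pd.DataFrame,
) -> float:
    """mmol carbon per gDW implied by the precursor demands."""
    carbons = (
        monomer_table.drop_duplicates("precursor").set_index("precursor")["carbons"].to_dict()
    )
    total = 0.0
    for cls in demands:
        for sp, v in demands[cls].items():
            total += v * float(carbons[sp])
    return total


def growth_rate_from_toc(toc_series: Sequence[tuple[float, float]]) -> GrowthRate:
    """Specific growth rate from total-organic-carbon measurements.

    Least-squares slope of ln(TOC) versus time (hours); the SD is the
    standard error of the slope.  Requires >= 2 time points and positive
    TOC throughout.
    """
    pts = [(float(t), float(c)) for t, c in toc_series]
    if len(pts) < 2:
        raise CompositionError("need at least two TOC time points")
    if any(c <= 0 for _, c in pts):
        raise CompositionError("TOC values must be positive")
    t = np.array([p[0] for p in pts])
    y = np.log([p[1] for p in pts])
    if np.allclose(y, y[0]):
        return GrowthRate(mu=0.0, sd=0.0)
    if len(pts) == 2:
        mu = (y[1] - y[0]) / (t[1] - t[0])
        return GrowthRate(mu=float(mu), sd=0.0)
    res = stats.linregress(t, y)
    return GrowthRate(mu=float(res.slope), sd=float(res.stderr))


def load_table_compositions(path=None) -> pd.DataFrame:
    """Bundled strain composition table (per strain and light condition)."""
    if path is None:
        path = resources.files("picoflux.data") / "strain_compositions.csv"
    return pd.read_csv(path, comment="#")
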