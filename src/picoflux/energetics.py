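"""ATP and NADPH energetics ledgers.

Translates a flux solution into cofactor demand totals: each reaction (or
biosynthetic sink) carries an ATP and NADPH cost per unit flux —
consumption positive, production negative, so an NADPH-producing step like
malic enzyme reduces the net NADPH demand.  A growth-independent
maintenance ATP term (default 2.85 mmol gDW^-1 h^-1, a value measured in
*Chlamydomonas reinhardtii*) is the only affine contribution.  NADH is
tracked as a separate currency and never folded into the NADPH total (no
transhydrogenase assumed).

Reference stoichiometries for comparison: linear electron flow (LEF)
produces ATP:NADPH at (12 H+ / 4 e-) x (3 ATP / 14 H+) / (2 NADPH / 4 e-)
= 1.29, while the Calvin-Benson-Bassham cycle consumes at 3 ATP / 2 NADPH
= 1.5 per CO2 fixed — the gap that cyclic electron flow has to close.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import pandas as pd

from .network import FluxVector

__all__ = [
    "EnergyCostTable",
    "EnergyLedger",
    "atp_nadph_demand",
    "lef_ratio",
    "cbb_ratio",
    "load_cost_table",
    "DEFAULT_MAINTENANCE_ATP",
]

logger = logging.getLogger(__name__)

#: mmol ATP gDW^-1 h^-1, maintenance requirement (C. reinhardtii literature value)
DEFAULT_MAINTENANCE_ATP = 2.85


@dataclass
class EnergyCostTable:
    """Per-reaction cofactor costs (positive = consumed per unit flux)."""

    atp: dict[str, float] = field(default_factory=dict)
    nadph: dict[str, float] = field(default_factory=dict)
    nadh: dict[str, float] = field(default_factory=dict)
    pathway: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EnergyCostTable":
        t = cls()
        for _, row in df.iterrows():
            rid = row["reaction"]
            t.atp[rid] = float(row.get("atp", 0.0) or 0.0)
            t.nadph[rid] = float(row.get("nadph", 0.0) or 0.0)
            t.nadh[rid] = float(row.get("nadh", 0.0) or 0.0)
            t.pathway[rid] = str(row.get("pathway", "") or "")
        return t


@dataclass
class EnergyLedger:
    """Demand totals in mmol gDW^-1 h^-1; ratio is ATP/NADPH (None if NADPH <= 0)."""

    atp: float
    nadph: float
    nadh: float
    maintenance: float
    ratio: float | None
    by_pathway: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def ratio_defined(self) -> bool:
        return self.ratio is not None


def atp_nadph_demand(
    fluxes: FluxVector,
    costs: EnergyCostTable,
    maintenance_atp: float = DEFAULT_MAINTENANCE_ATP,
) -> EnergyLedger:
    """Cofactor demand ledger for a flux solution.

    ATP = sum_i v_i * atp_i + maintenance; NADPH = sum_i v_i * nadph_i.
    Reactions with flux but no cost entry default to zero cost with a
    logged warning.  A nonpositive NADPH total flags the ratio as
    undefined rather than raising.
    """
    if maintenance_atp < 0:
        raise ValueError("maintenance ATP must be nonnegative")
    atp = maintenance_atp
    nadph = 0.0
    nadh = 0.0
    by_pathway: dict[str, dict[str, float]] = {
        "maintenance": {"atp": maintenance_atp, "nadph": 0.0, "nadh": 0.0}
    }
    known = set(costs.atp) | set(costs.nadph) | set(costs.nadh)
    for rid, v in fluxes.net.items():
        if rid not in known:
            if abs(v) > 1e-9:
                logger.warning("no cofactor cost entry for flux-carrying reaction %s", rid)
            continue
        a = v * costs.atp.get(rid, 0.0)
        p = v * costs.nadph.get(rid, 0.0)
        h = v * costs.nadh.get(rid, 0.0)
        atp += a
        nadph += p
        nadh += h
        pw = costs.pathway.get(rid, "") or "other"
        slot = by_pathway.setdefault(pw, {"atp": 0.0, "nadph": 0.0, "nadh": 0.0})
        slot["atp"] += a
        slot["nadph"] += p
        slot["nadh"] += h
    ratio = atp / nadph if nadph > 0 else None
    return EnergyLedger(
        atp=atp,
        nadph=nadph,
        nadh=nadh,
        maintenance=maintenance_atp,
        ratio=ratio,
        by_pathway=by_pathway,
    )


def lef_ratio(
    protons_per_4e: float = 12.0,
    atp_per_14h: float = 3.0,
    nadph_per_4e: float = 2.0,
) -> float:
    """ATP:NADPH output ratio of linear electron flow.

    Defaults: 12 protons translocated and 2 NADPH produced per 4 electrons,
    with the ATP synthase making 3 ATP per 14 protons -> 12 * 3/14 / 2 =
    1.2857..., conventionally quoted as 1.29.
    """
    if min(protons_per_4e, atp_per_14h, nadph_per_4e) <= 0:
        raise ValueError("stoichiometries must be positive")
    return (protons_per_4e * atp_per_14h / 14.0) / nadph_per_4e


def cbb_ratio(atp_per_co2: float = 3.0, nadph_per_co2: float = 2.0) -> float:
    """ATP:NADPH consumption ratio of the CBB cycle (3 ATP, 2 NADPH per CO2)."""
    if min(atp_per_co2, nadph_per_co2) <= 0:
        raise ValueError("stoichiometries must be positive")
    return atp_per_co2 / nadph_per_co2


def load_cost_table(path=None) -> EnergyCostTable:
    """Bundled cofactor cost table for the core scenario network."""
    if path is None:
        path = resources.files("picoflux.data") / "costs_core.csv"
    return EnergyCostTable.from_frame(pd.read_csv(path, comment="#"))


#: literature-typical polymerization + monomer-synthesis costs per mmol of
#: precursor drained into each macromolecule class: (ATP, NADPH).
#: Protein dominates: ~4.3 ATP per residue for activation + elongation and
#: ~1 NADPH for amino-acid synthesis; fatty-acid synthesis takes 1 ATP +
#: 2 NADPH per C2 unit.
DEFAULT_SINK_COSTS: dict[str, tuple[float, float]] = {
    "carbohydrate": (1.0, 0.0),
    "protein": (4.3, 1.0),
    "fame": (1.0, 2.0),
    "dna": (1.0, 0.1),
    "rna": (1.0, 0.1),
    "chla": (1.0, 0.4),
}


def sink_cost_entries(
    demands: Mapping[str, Mapping[str, float]],
    per_class: Mapping[str, tuple[float, float]] | None = None,
) -> EnergyCostTable:
    """Cofactor costs of the biomass sink reactions, per unit sink flux.

    A sink's flux equals the growth rate, so its cost per flux unit is the
    per-precursor cost summed over the class's demand coefficients
    (mmol precursor per gDW).  Merge the result with the per-reaction
    table via :func:`merge_cost_tables`.
    """
    per_class = dict(DEFAULT_SINK_COSTS, **(per_class or {}))
    out = EnergyCostTable()
    for cls, coeffs in demands.items():
        atp_unit, nadph_unit = per_class.get(cls, (0.0, 0.0))
        total = sum(coeffs.values())
        rid = f"sink_{cls}"
        out.atp[rid] = atp_unit * total
        out.nadph[rid] = nadph_unit * total
        out.nadh[rid] = 0.0
        out.pathway[rid] = "biomass"
    return out


def merge_cost_tables(*tables: EnergyCostTable) -> EnergyCostTable:
    merged = EnergyCostTable()
    for t in tables:
        merged.atp.update(t.atp)
        merged.nadph.update(t.nadph)
        merged.nadh.update(t.nadh)
        merged.pathway.update(t.pathway)
    return merged
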