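"""Measurement containers and file dialects.

The MID dialect is a long-format CSV with columns ``metabolite, fragment,
mass_shift, time_s, replicate, mole_fraction, sd``; the writer emits the
same dialect the fitter reads.  ``fragment`` is the canonical EMU string
``SPECIES{p1,p2,...}``; replicate is an integer or ``mean`` for
replicate-aggregated rows.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .emu import EMU

__all__ = ["MeasurementSet", "emu_from_string", "read_mid_csv", "write_mid_csv"]

_EMU_RE = re.compile(r"^(?P<sp>[A-Za-z0-9_.]+)\{(?P<pos>[\d,]+)\}$")


def emu_from_string(text: str) -> EMU:
    m = _EMU_RE.match(text.strip())
    if not m:
        raise ValueError(f"cannot parse EMU string {text!r}")
    return EMU(m.group("sp"), tuple(int(p) for p in m.group("pos").split(",")))


@dataclass
class MeasurementSet:
    """Replicate-aggregated MID observations with SDs.

    ``frame`` columns: metabolite, fragment, mass_shift, time_s,
    mole_fraction, sd.  SDs are floored (default 0.005 mole fraction) when
    building residuals, not here.  ``growth_rate`` (h^-1) and the biomass
    composition travel with the measurements because they constrain the
    sink fluxes during fitting.
    """

    frame: pd.DataFrame
    growth_rate: float = 0.0
    growth_rate_sd: float = 0.0
    composition: Mapping[str, float] | None = None
    replicates: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        required = {"metabolite", "fragment", "mass_shift", "time_s", "mole_fraction", "sd"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"measurement frame missing columns: {sorted(missing)}")

    @property
    def times(self) -> np.ndarray:
        return np.array(sorted(self.frame.time_s.unique()), float)

    @property
    def fragments(self) -> list[EMU]:
        return sorted({emu_from_string(f) for f in self.frame.fragment.unique()})

    @property
    def n_observations(self) -> int:
        return len(self.frame)


def write_mid_csv(measurements: MeasurementSet, path) -> None:
    df = measurements.frame.copy()
    if "replicate" not in df.columns:
        df.insert(4, "replicate", "mean")
    with open(path, "w", encoding="utf-8") as fh:
        for k, v in measurements.meta.items():
            fh.write(f"# {k}: {json.dumps(v) if not isinstance(v, str) else v}\n")
        fh.write(f"# growth_rate: {measurements.growth_rate}\n")
        fh.write(f"# growth_rate_sd: {measurements.growth_rate_sd}\n")
        if measurements.composition:
            fh.write(f"# composition: {json.dumps(dict(measurements.composition))}\n")
        df.to_csv(fh, index=False)


def read_mid_csv(path) -> MeasurementSet:
    meta: dict = {}
    growth_rate = 0.0
    growth_rate_sd = 0.0
    composition = None
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    header_end = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            m = re.match(r"#\s*([A-Za-z_]+)\s*:\s*(.*)", line)
            if m:
                key, val = m.group(1), m.group(2).strip()
                if key == "growth_rate":
                    growth_rate = float(val)
                elif key == "growth_rate_sd":
                    growth_rate_sd = float(val)
                elif key == "composition":
                    composition = json.loads(val)
                else:
                    meta[key] = val
            header_end = i + 1
        else:
            break
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[header_end:])))
    if "replicate" in df.columns:
        reps = df[df.replicate.astype(str) != "mean"]
        agg = df[df.replicate.astype(str) == "mean"].drop(columns=["replicate"])
        if agg.empty and not reps.empty:
            agg = _aggregate_replicates(reps)
        replicates = reps if not reps.empty else None
    else:
        agg, replicates = df, None
    return MeasurementSet(
        frame=agg.reset_index(drop=True),
        growth_rate=growth_rate,
        growth_rate_sd=growth_rate_sd,
        composition=composition,
        replicates=replicates,
        meta=meta,
    )


def _aggregate_replicates(reps: pd.DataFrame) -> pd.DataFrame:
    keys = ["metabolite", "fragment", "mass_shift", "time_s"]
    g = reps.groupby(keys)["mole_fraction"]
    out = g.agg(mole_fraction="mean").reset_index()
    n = g.size().reset_index(name="n")["n"]
    sd = g.std(ddof=1).reset_index(name="sd")["sd"]
    out["sd"] = (sd / np.sqrt(n)).fillna(0.0)
    return out
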