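"""End-to-end orchestration with structured configuration and provenance.

A :class:`RunConfig` (YAML on disk, flat keys) drives the chain:
load-or-generate measurements -> multi-start flux fit -> CO2-normalized
flux map -> ATP/NADPH ledger.  Every output embeds the package version,
a hash of the configuration, and the master seed, so a rerun with the
same config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from . import __version__
from .energetics import DEFAULT_MAINTENANCE_ATP, atp_nadph_demand, load_cost_table
from .fit import fit_fluxes, fit_report_frame, normalize_to_co2
from .io import read_mid_csv, write_mid_csv
from .simulate import LabelInput
from .synthetic import generate_experiment, scenario, scenario_fit_config

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Flat pipeline configuration; unknown keys are rejected."""

    output_dir: str = "picoflux_run"
    seed: int = 0
    # either a bundled scenario ...
    scenario: str | None = None
    # ... or explicit inputs
    network: str | None = None
    mids: str | None = None
    free_anchors: tuple[str, ...] = ()
    tracer: str = "CO2.x"
    # fit settings
    starts: int = 20
    sd_floor: float = 0.005
    max_nfev: int = 60
    natural_abundance: float | None = 0.0107
    # energetics
    costs: str | None = None
    maintenance_atp: float = DEFAULT_MAINTENANCE_ATP

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise PipelineError("config", f"unknown keys: {sorted(unknown)}")
        if "free_anchors" in data:
            data["free_anchors"] = tuple(data["free_anchors"])
        return cls(**data)

    def digest(self) -> str:
        payload = asdict(self)
        payload.pop("output_dir", None)  # where results land must not change them
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Run fit -> normalize -> energetics and write the artifact bundle.

    Returns the machine-readable summary (also written as summary.json).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("picoflux")
    root.addHandler(handler)
    try:
        return _run(config, out)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, out: Path) -> dict:
    provenance = {
        "tool": "picoflux",
        "version": __version__,
        "config_hash": config.digest(),
        "seed": config.seed,
    }

    # ---- inputs
    scn = None
    if config.scenario:
        scn = scenario(config.scenario, seed=config.seed)
        emunet = scn.emu_network()
        measurements, truth = generate_experiment(scn, seed=config.seed, emunet=emunet)
        net = scn.network
        label = scn.label
        fit_cfg = scenario_fit_config(
            scn,
            starts=config.starts,
            seed=config.seed,
            sd_floor=config.sd_floor,
            max_nfev=config.max_nfev,
        )
        write_mid_csv(measurements, out / "measurements.csv")
    else:
        if not config.network or not config.mids:
            raise PipelineError("config", "need either scenario or network+mids paths")
        for p in (config.network, config.mids):
            if not Path(p).exists():
                raise PipelineError("config", f"input path does not exist: {p}")
        from .network import parse_network
        from .emu import decompose
        from .fit import FitConfig

        net = parse_network(config.network)
        measurements = read_mid_csv(config.mids)
        targets = sorted({f for f in measurements.frame.metabolite.unique()})
        emunet = decompose(net, targets)
        label = LabelInput(config.tracer)
        fit_cfg = FitConfig(
            starts=config.starts,
            seed=config.seed,
            sd_floor=config.sd_floor,
            max_nfev=config.max_nfev,
            natural_abundance=config.natural_abundance,
            free_anchors=tuple(config.free_anchors),
        )

    # ---- fit
    try:
        fit = fit_fluxes(net, emunet, measurements, fit_cfg, label=label)
    except Exception as exc:
        raise PipelineError("fit", str(exc)) from exc
    logger.info("fit finished: %s", fit.summary()["ssr_bracket"])

    # ---- normalize
    norm = normalize_to_co2(fit.fluxes, fit.co2_uptake)
    report = fit_report_frame(fit)
    report.insert(0, "provenance", provenance["config_hash"])

    # ---- energetics
    try:
        if scn is not None:
            from .synthetic import scenario_cost_table

            costs = scenario_cost_table(scn, config.costs)
        else:
            costs = load_cost_table(config.costs)
        ledger = atp_nadph_demand(fit.fluxes, costs, config.maintenance_atp)
    except Exception as exc:
        raise PipelineError("energetics", str(exc)) from exc

    summary = {
        **provenance,
        **fit.summary(),
        "normalized_co2_uptake": norm.net[fit.model.uptake_reaction],
        "atp_demand": ledger.atp,
        "nadph_demand": ledger.nadph,
        "atp_nadph_ratio": ledger.ratio,
        "maintenance_atp": ledger.maintenance,
    }
    report.to_csv(out / "fit_report.csv", index=False)
    with open(out / "normalized_fluxes.json", "w", encoding="utf-8") as fh:
        json.dump({**provenance, "normalized_net": norm.net}, fh, indent=2, sort_keys=True)
    with open(out / "energy_ledger.json", "w", encoding="utf-8") as fh:
        json.dump(
            {**provenance, "by_pathway": ledger.by_pathway, "atp": ledger.atp,
             "nadph": ledger.nadph, "nadh": ledger.nadh, "ratio": ledger.ratio},
            fh, indent=2, sort_keys=True,
        )
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
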