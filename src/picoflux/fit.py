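"""Flux estimation from transient MID measurements.

Weighted least squares over the steady-state flux manifold: net fluxes are
parameterized through the null-space basis (every candidate satisfies
S v = b exactly), exchange fluxes through the bounded ratio r = e/(1+e) in
[0, 1), pool sizes on a log scale, and optional inactive-pool dilution
fractions.  The optimizer is scipy's trust-region-reflective
``least_squares`` restarted from many random initial guesses; fit quality
is judged by the sum of squared SD-weighted residuals (SSR) against the
central chi-square acceptance range, and per-parameter confidence
intervals come from parameter continuation: walk the parameter, re-optimize
everything else, and find where SSR crosses SSR_min + chi2(1, level).

Net CO2 uptake is read off the fitted solution — the biomass sink demands
fix it through the network balance; it is never an input.  Flux maps are
reported normalized to 100 units of CO2 taken up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .emu import EMUNetwork
from .io import MeasurementSet, emu_from_string
from .network import (
    FluxVector,
    FreeFluxBasis,
    ReactionNetwork,
    free_flux_basis,
    theta_bounds_lp,
)
from .simulate import LabelInput, MIDTimecourse, make_time_grid, simulate_labeling

__all__ = [
    "FitConfig",
    "FitResult",
    "ConfidenceInterval",
    "NormalizedFluxMap",
    "ssr",
    "fit_fluxes",
    "chi_square_range",
    "profile_ci",
    "profile_ci_objective",
    "normalize_to_co2",
]


class FitError(RuntimeError):
    pass


@dataclass
class FitConfig:
    """Knobs of the flux estimator (defaults follow standard practice)."""

    starts: int = 20
    seed: int = 0
    sd_floor: float = 0.005  # mole fraction; triplicate SDs are unstable
    max_flux: float = 50.0  # mmol gDW^-1 h^-1 box for LP bounds
    exch_ratio_max: float = 0.99  # r = e/(1+e) upper bound
    pool_bounds: tuple[float, float] = (1e-3, 1e3)  # umol gDW^-1
    pool_start_range: tuple[float, float] = (-1.5, 1.5)  # log10, random starts
    fit_dilutions: bool = False
    dilution_max: float = 0.95
    #: species -> group name; members of a group share one fitted pool size
    #: (standard for co-located pools with no independent labeling signal,
    #: e.g. the compartmental CO2 pools)
    pool_groups: Mapping[str, str] | None = None
    method: str = "bdf2"
    natural_abundance: float | None = None
    free_anchors: tuple[str, ...] = ()
    uptake_reaction: str | None = None  # autodetected from source reactions
    max_nfev: int = 60
    ftol: float = 1e-10
    xtol: float = 1e-10
    alpha: float = 0.05


@dataclass
class ConfidenceInterval:
    parameter: str
    level: float
    lower: float  # -inf when the walk hit the parameter bound
    upper: float  # +inf likewise
    point: float

    @property
    def bounded(self) -> bool:
        return math.isfinite(self.lower) and math.isfinite(self.upper)

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


@dataclass
class NormalizedFluxMap:
    """Net fluxes rescaled so net CO2 uptake is exactly 100 units."""

    net: dict[str, float]
    factor: float
    co2_uptake: float

    def scale_ci(self, ci: ConfidenceInterval) -> ConfidenceInterval:
        return ConfidenceInterval(
            ci.parameter,
            ci.level,
            ci.lower * self.factor,
            ci.upper * self.factor,
            ci.point * self.factor,
        )


def chi_square_range(df: int, alpha: float = 0.05) -> tuple[float, float]:
    """Central (1 - alpha) chi-square acceptance interval for the SSR."""
    if df < 1 or int(df) != df:
        raise ValueError("df must be a positive integer")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    return (
        float(stats.chi2.ppf(alpha / 2.0, df)),
        float(stats.chi2.ppf(1.0 - alpha / 2.0, df)),
    )


def ssr(simulated: MIDTimecourse, measured: MeasurementSet, sd_floor: float = 0.005) -> float:
    """Sum of squared SD-weighted residuals between simulation and data."""
    frame = measured.frame
    times = list(simulated.times)
    total = 0.0
    for frag, grp in frame.groupby("fragment"):
        emu = emu_from_string(frag)
        if emu not in simulated.data:
            raise FitError(f"measurement {frag} has no simulated counterpart")
        arr = simulated.data[emu]
        for _, row in grp.iterrows():
            if row.time_s not in times:
                raise FitError(f"time {row.time_s} s not on the simulation grid")
            it = times.index(row.time_s)
            sd = max(float(row.sd), sd_floor)
            total += ((arr[it, int(row.mass_shift)] - row.mole_fraction) / sd) ** 2
    return float(total)


# ---------------------------------------------------------------------------
# model internals


class FitModel:
    """Packs/unpacks the parameter vector and evaluates weighted residuals."""

    def __init__(
        self,
        net: ReactionNetwork,
        emunet: EMUNetwork,
        measurements: MeasurementSet,
        label: LabelInput,
        config: FitConfig,
    ):
        self.net = net
        self.emunet = emunet
        self.measurements = measurements
        self.label = label
        self.config = config
        self.basis: FreeFluxBasis = free_flux_basis(net, prefer=config.free_anchors)
        self.theta_box = (
            theta_bounds_lp(self.basis, net, config.max_flux)
            if self.basis.dim
            else []
        )
        self.reversible = [r.id for r in net.reactions if r.reversible]
        needed = sorted({e.species for s in emunet.sizes for e in emunet.emus_by_size[s]})
        self.pool_species = needed
        groups = dict(config.pool_groups or {})
        self.pool_group_of = {s: groups.get(s, s) for s in needed}
        self.pool_params = sorted(set(self.pool_group_of.values()))
        self.measured_species = sorted({e.species for e in emunet.targets})
        self.dil_species = (
            [s for s in net.dilution_species if s in self.measured_species]
            if config.fit_dilutions
            else []
        )
        self.times = measurements.times
        self.grid = make_time_grid(self.times)
        self._build_extractor()
        # source reaction whose net flux is the CO2 uptake
        if config.uptake_reaction:
            self.uptake_reaction = config.uptake_reaction
        else:
            sources = [r.id for r in net.reactions if r.kind == "source"]
            if len(sources) != 1:
                raise FitError(
                    f"cannot autodetect uptake reaction among {sources}; set "
                    "config.uptake_reaction"
                )
            self.uptake_reaction = sources[0]

    # -- parameter vector layout: [theta | exch ratios | log10 pools | dilutions]

    @property
    def n_params(self) -> int:
        return (
            self.basis.dim
            + len(self.reversible)
            + len(self.pool_params)
            + len(self.dil_species)
        )

    def param_names(self) -> list[str]:
        names = [f"flux:{r}" for r in self.basis.free_reactions]
        if not names and self.basis.dim:
            names = [f"theta:{i}" for i in range(self.basis.dim)]
        names += [f"exch:{r}" for r in self.reversible]
        names += [f"pool:{g}" for g in self.pool_params]
        names += [f"dil:{s}" for s in self.dil_species]
        return names

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = [], []
        for lb, ub in self.theta_box:
            lo.append(lb)
            hi.append(ub)
        c = self.config
        lo += [0.0] * len(self.reversible)
        hi += [c.exch_ratio_max] * len(self.reversible)
        lo += [math.log10(c.pool_bounds[0])] * len(self.pool_params)
        hi += [math.log10(c.pool_bounds[1])] * len(self.pool_params)
        lo += [0.0] * len(self.dil_species)
        hi += [c.dilution_max] * len(self.dil_species)
        return np.array(lo), np.array(hi)

    def unpack(self, x: np.ndarray):
        k = self.basis.dim
        m = len(self.reversible)
        p = len(self.pool_params)
        theta = x[:k]
        ratios = x[k : k + m]
        pools_log = x[k + m : k + m + p]
        dil = x[k + m + p :]
        exchange = {
            rid: float(r / (1.0 - r)) for rid, r in zip(self.reversible, ratios)
        }
        fluxes = self.basis.flux_vector(theta, exchange=exchange)
        group_val = dict(zip(self.pool_params, pools_log))
        pools = {
            s: float(10.0 ** group_val[self.pool_group_of[s]]) for s in self.pool_species
        }
        dilution = {s: float(d) for s, d in zip(self.dil_species, dil)}
        return fluxes, pools, dilution

    def pack(
        self,
        fluxes: FluxVector,
        pools: Mapping[str, float],
        dilution: Mapping[str, float] | None = None,
    ) -> np.ndarray:
        theta = [fluxes.net[r] for r in self.basis.free_reactions]
        ratios = []
        for rid in self.reversible:
            e = fluxes.exchange.get(rid, 0.0)
            ratios.append(e / (1.0 + e))
        members: dict[str, list[float]] = {}
        for s in self.pool_species:
            members.setdefault(self.pool_group_of[s], []).append(math.log10(pools[s]))
        plog = [float(np.mean(members[g])) for g in self.pool_params]
        dil = [float((dilution or {}).get(s, 0.0)) for s in self.dil_species]
        return np.array(theta + ratios + plog + dil)

    def _build_extractor(self):
        frame = self.measurements.frame
        times = list(self.times)
        self._obs = frame.mole_fraction.to_numpy(float)
        self._sd = np.maximum(frame.sd.to_numpy(float), self.config.sd_floor)
        self._slices = []
        row_pos = 0
        order = []
        for frag, grp in frame.groupby("fragment", sort=False):
            emu = emu_from_string(frag)
            if emu not in self.emunet.targets and emu not in [
                e for s in self.emunet.sizes for e in self.emunet.emus_by_size[s]
            ]:
                raise FitError(f"measurement {frag} has no simulated counterpart")
            t_idx = np.array([times.index(t) for t in grp.time_s])
            k_idx = grp.mass_shift.to_numpy(int)
            rows = grp.index.to_numpy()
            self._slices.append((emu, t_idx, k_idx, rows))
            order.extend(rows.tolist())
        self._n_obs = len(frame)

    def residuals(self, x: np.ndarray) -> np.ndarray:
        fluxes, pools, dilution = self.unpack(x)
        sim = simulate_labeling(
            self.net,
            self.emunet,
            fluxes,
            pools,
            self.label,
            times=self.times,
            dilution=dilution,
            natural_abundance=self.config.natural_abundance,
            method=self.config.method,
            grid=self.grid,
            check_steady_state=False,
        )
        yhat = np.empty(self._n_obs)
        for emu, t_idx, k_idx, rows in self._slices:
            yhat[rows] = sim.data[emu][t_idx, k_idx]
        return (yhat - self._obs) / self._sd

    def ssr_at(self, x: np.ndarray) -> float:
        r = self.residuals(x)
        return float(r @ r)

    def random_start(self, rng: np.random.Generator) -> np.ndarray:
        x = []
        for lb, ub in self.theta_box:
            x.append(rng.uniform(lb, ub))
        x += rng.uniform(0.0, 0.7, len(self.reversible)).tolist()
        lo, hi = self.config.pool_start_range
        x += rng.uniform(lo, hi, len(self.pool_params)).tolist()
        x += rng.uniform(0.0, 0.3, len(self.dil_species)).tolist()
        return np.array(x)


@dataclass
class FitResult:
    fluxes: FluxVector
    pools: dict[str, float]
    dilution: dict[str, float]
    ssr: float
    df: int
    chi2_range: tuple[float, float]
    co2_uptake: float
    start_trace: list[tuple[int, float]]
    seed: int
    x: np.ndarray
    model: FitModel = field(repr=False)

    @property
    def acceptable(self) -> bool:
        lo, hi = self.chi2_range
        return lo <= self.ssr <= hi

    def summary(self) -> dict:
        return {
            "ssr": self.ssr,
            "df": self.df,
            "chi2_lo": self.chi2_range[0],
            "chi2_hi": self.chi2_range[1],
            "ssr_bracket": f"SSR = {self.ssr:.1f} [{self.chi2_range[0]:.1f}, "
            f"{self.chi2_range[1]:.1f}]",
            "co2_uptake": self.co2_uptake,
            "seed": self.seed,
            "n_starts": len(self.start_trace),
        }


def fit_fluxes(
    net: ReactionNetwork,
    emunet: EMUNetwork,
    measurements: MeasurementSet,
    config: FitConfig | None = None,
    label: LabelInput | None = None,
    x0: np.ndarray | Sequence[float] | None = None,
) -> FitResult:
    """Multi-start bounded least squares over fluxes, pools and dilutions.

    Sink fluxes fixed on ``net`` (biomass demands x growth rate) constrain
    the steady-state manifold; the free coordinates, exchange ratios, log
    pool sizes and dilution fractions are optimized against the measured
    MIDs.  The lowest-SSR start wins (ties broken by start index).  When
    ``x0`` is given it is used for the first start and random draws fill
    the rest — useful for warm-started refits and calibration studies.
    """
    config = config or FitConfig()
    label = label or LabelInput("CO2.x")
    model = FitModel(net, emunet, measurements, label, config)
    lo, hi = model.bounds()
    rng = np.random.default_rng(config.seed)

    best = None
    trace: list[tuple[int, float]] = []
    n_fail = 0
    for start in range(config.starts):
        if start == 0 and x0 is not None:
            xs = np.clip(np.asarray(x0, float), lo, hi)
        else:
            xs = model.random_start(rng)
        try:
            res = least_squares(
                model.residuals,
                xs,
                bounds=(lo, hi),
                method="trf",
                x_scale="jac",
                ftol=config.ftol,
                xtol=config.xtol,
                max_nfev=config.max_nfev,
            )
        except Exception:
            n_fail += 1
            continue
        s = float(2.0 * res.cost)
        trace.append((start, s))
        if best is None or s < best[1] - 1e-12:
            best = (start, s, res.x)
    if best is None:
        raise FitError(f"all {config.starts} starts failed to converge")

    _, best_ssr, best_x = best
    fluxes, pools, dilution = model.unpack(best_x)
    df = model._n_obs - model.n_params
    if df <= 0:
        raise FitError(
            f"nonpositive degrees of freedom ({model._n_obs} observations, "
            f"{model.n_params} parameters)"
        )
    return FitResult(
        fluxes=fluxes,
        pools=pools,
        dilution=dilution,
        ssr=best_ssr,
        df=df,
        chi2_range=chi_square_range(df, config.alpha),
        co2_uptake=float(fluxes.net[model.uptake_reaction]),
        start_trace=trace,
        seed=config.seed,
        x=best_x,
        model=model,
    )


# ---------------------------------------------------------------------------
# profile-likelihood confidence intervals (parameter continuation)


def profile_ci_objective(
    objective,
    x_best: np.ndarray,
    index: int,
    bounds: tuple[np.ndarray, np.ndarray],
    refit,
    level: float = 0.95,
    step_frac: float = 0.02,
    max_steps: int = 25,
    bisections: int = 6,
) -> tuple[float, float]:
    """Generic parameter-continuation walk on any SSR-like objective.

    ``objective(x) -> ssr``; ``refit(index, value, x_start) -> (ssr, x)``
    re-optimizes all other coordinates with coordinate ``index`` pinned.
    Walks outward with a step that starts at ``step_frac`` of the parameter
    scale and doubles, until SSR exceeds SSR_min + chi2(1, level); the
    crossing is located by linear interpolation.  A walk that reaches the
    parameter bound before crossing reports that side as unbounded
    (-inf / +inf).
    """
    lo, hi = bounds
    x0 = np.asarray(x_best, float)
    s0 = objective(x0)
    thresh = s0 + float(stats.chi2.ppf(level, 1))
    span = hi[index] - lo[index]
    scale = max(abs(x0[index]), 1e-3 * span if math.isfinite(span) else 1.0, 1e-8)

    out = []
    for direction in (-1.0, +1.0):
        step = step_frac * scale
        prev_val, prev_ssr = x0[index], s0
        x_start = x0.copy()
        bound = lo[index] if direction < 0 else hi[index]
        crossing = None
        bracket = None  # (inside_val, inside_ssr, inside_x, outside_val, outside_ssr)
        for _ in range(max_steps):
            val = prev_val + direction * step
            hit_bound = (direction < 0 and val <= bound) or (
                direction > 0 and val >= bound
            )
            if hit_bound:
                val = bound
            s, x_start = refit(index, val, x_start)
            if s >= thresh:
                bracket = (prev_val, prev_ssr, x_start, val, s)
                break
            if hit_bound:
                crossing = -math.inf if direction < 0 else math.inf
                break
            prev_val, prev_ssr = val, s
            step *= 2.0
        if bracket is not None:
            in_val, in_ssr, x_in, out_val, out_ssr = bracket
            # bisect the bracket; the SSR profile can be far from quadratic
            for _ in range(bisections):
                if abs(out_val - in_val) <= 0.05 * step_frac * scale:
                    break
                mid = 0.5 * (in_val + out_val)
                s_mid, x_in = refit(index, mid, x_in)
                if s_mid >= thresh:
                    out_val, out_ssr = mid, s_mid
                else:
                    in_val, in_ssr = mid, s_mid
            frac = (thresh - in_ssr) / max(out_ssr - in_ssr, 1e-12)
            crossing = in_val + (out_val - in_val) * frac
        elif crossing is None:  # ran out of steps without crossing
            crossing = -math.inf if direction < 0 else math.inf
        out.append(crossing)
    return out[0], out[1]


def profile_ci(
    fit: FitResult,
    parameter: str,
    level: float = 0.95,
    step_frac: float = 0.02,
    max_steps: int = 25,
    refit_max_nfev: int = 15,
    bisections: int = 6,
) -> ConfidenceInterval:
    """Profile-likelihood CI for one fitted parameter.

    ``parameter`` is a name from ``fit.model.param_names()`` — e.g.
    ``"flux:akgsuc"``, ``"exch:mdh"``, ``"pool:AKG.m"`` — or a bare
    reaction id that is one of the free flux coordinates.
    """
    model = fit.model
    names = model.param_names()
    key = parameter if parameter in names else f"flux:{parameter}"
    if key not in names:
        raise KeyError(f"unknown parameter {parameter!r}; choose from {names}")
    index = names.index(key)
    lo, hi = model.bounds()

    def refit(idx, value, x_start):
        free = [i for i in range(len(x_start)) if i != idx]
        xf0 = np.clip(x_start[free], lo[free], hi[free])

        def resid(xf):
            x = x_start.copy()
            x[idx] = value
            x[free] = xf
            return model.residuals(x)

        try:
            res = least_squares(
                resid,
                xf0,
                bounds=(lo[free], hi[free]),
                method="trf",
                x_scale="jac",
                ftol=1e-8,
                xtol=1e-8,
                max_nfev=refit_max_nfev,
            )
            x = x_start.copy()
            x[idx] = value
            x[free] = res.x
            return float(2.0 * res.cost), x
        except Exception:
            return math.inf, x_start

    lower, upper = profile_ci_objective(
        model.ssr_at,
        fit.x,
        index,
        (lo, hi),
        refit,
        level=level,
        step_frac=step_frac,
        max_steps=max_steps,
        bisections=bisections,
    )
    # a lower bound that walked into the box floor of a nonnegative flux is 0
    if lower == -math.inf and lo[index] == 0.0:
        lower = 0.0
    return ConfidenceInterval(
        parameter=key,
        level=level,
        lower=lower,
        upper=upper,
        point=float(fit.x[index]),
    )


def normalize_to_co2(fluxes: FluxVector, co2_uptake: float) -> NormalizedFluxMap:
    """Rescale net fluxes so that net CO2 uptake reads exactly 100 units."""
    if co2_uptake <= 0:
        raise ValueError("CO2 uptake must be positive to normalize")
    factor = 100.0 / co2_uptake
    return NormalizedFluxMap(
        net={k: v * factor for k, v in fluxes.net.items()},
        factor=factor,
        co2_uptake=co2_uptake,
    )


def fit_report_frame(
    fit: FitResult,
    cis: Mapping[str, ConfidenceInterval] | None = None,
) -> pd.DataFrame:
    """Per-reaction report: net flux, exchange, 95% CI, normalized flux."""
    norm = normalize_to_co2(fit.fluxes, fit.co2_uptake)
    rows = []
    for rid in fit.model.basis.reaction_ids:
        ci = (cis or {}).get(rid) or (cis or {}).get(f"flux:{rid}")
        rows.append(
            {
                "reaction": rid,
                "net_flux": fit.fluxes.net.get(rid, 0.0),
                "exchange": fit.fluxes.exchange.get(rid, 0.0),
                "lo95": ci.lower if ci else np.nan,
                "hi95": ci.upper if ci else np.nan,
                "normalized": norm.net.get(rid, 0.0),
            }
        )
    return pd.DataFrame(rows)
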