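"""Chlorophyll-fluorescence utilities.

Small, self-contained computations used alongside the flux analysis:
non-photochemical quenching NPQ = (Fm - Fm')/Fm' from dark- and
light-adapted maximal fluorescence, light-response curve aggregation,
the single-turnover flashlet schedule of a fast-repetition-rate
fluorometer, and the two-sample test used for inhibitor comparisons.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FluorescenceRecord",
    "FlashSchedule",
    "npq",
    "npq_curve",
    "st_flash_schedule",
    "inhibitor_effect_test",
    "TTestResult",
]


@dataclass(frozen=True)
class FluorescenceRecord:
    intensity: float  # actinic light, umol m^-2 s^-1
    fm: float  # dark-adapted maximal fluorescence
    fm_prime: float  # light-adapted maximal fluorescence
    replicate: int = 0
    treatment: str = "control"  # control | OG | AA


@dataclass(frozen=True)
class FlashSchedule:
    """Ordered flashlet delay intervals in microseconds with phase labels."""

    delays_us: tuple[float, ...]
    phases: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.delays_us)


def npq(fm: float, fm_prime: float) -> float:
    """Non-photochemical quenching, (Fm - Fm')/Fm'.

    Scale-invariant in (Fm, Fm'); requires Fm' > 0.
    """
    if fm_prime <= 0:
        raise ValueError("Fm' must be positive")
    return (fm - fm_prime) / fm_prime


def npq_curve(records: Iterable[FluorescenceRecord]) -> pd.DataFrame:
    """Per-intensity NPQ mean +/- SD, ordered by actinic intensity.

    Mixing treatments within one intensity group is an error — group or
    filter the records by treatment first.  Single-record groups get SD
    NaN (flagged, not zero).
    """
    recs = list(records)
    if not recs:
        raise ValueError("no records")
    df = pd.DataFrame(
        {
            "intensity": [r.intensity for r in recs],
            "treatment": [r.treatment for r in recs],
            "npq": [npq(r.fm, r.fm_prime) for r in recs],
        }
    )
    for intensity, grp in df.groupby("intensity"):
        if grp.treatment.nunique() > 1:
            raise ValueError(
                f"mixed treatments at intensity {intensity}: "
                f"{sorted(grp.treatment.unique())}"
            )
    out = (
        df.groupby("intensity")["npq"]
        .agg(npq_mean="mean", npq_sd=lambda x: x.std(ddof=1) if len(x) > 1 else np.nan, n="size")
        .reset_index()
        .sort_values("intensity", ignore_index=True)
    )
    return out


def st_flash_schedule(
    n_excitation: int = 175,
    n_relaxation: int = 127,
    base_delay_us: float = 20.0,
    growth: float = 1.025,
    excitation_delay_us: float = 2.5,
    literal_power_formula: bool = False,
) -> FlashSchedule:
    """Single-turnover flashlet schedule: excitation burst then relaxation.

    Excitation flashlets fire at a constant delay; relaxation delays grow
    geometrically, j_i = base * growth**i.  ``literal_power_formula``
    switches to j_i = 10**(1.6 + growth*i) us, an alternative published
    parameterization whose delays exceed the age of the universe within a
    few flashlets and which is therefore not the default.
    """
    if n_excitation <= 0 or n_relaxation <= 0:
        raise ValueError("flashlet counts must be positive")
    if growth < 1.0:
        raise ValueError("relaxation growth factor must be >= 1")
    exc = [excitation_delay_us] * n_excitation
    if literal_power_formula:
        relax = [10.0 ** (1.6 + growth * i) for i in range(n_relaxation)]
    else:
        relax = [base_delay_us * growth**i for i in range(n_relaxation)]
    return FlashSchedule(
        delays_us=tuple(exc + relax),
        phases=tuple(["excitation"] * n_excitation + ["relaxation"] * n_relaxation),
    )


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    pvalue: float
    variant: str
    degenerate: bool = False


def inhibitor_effect_test(
    control: Sequence[float],
    treated: Sequence[float],
    equal_var: bool = False,
) -> TTestResult:
    """Two-sided two-sample t test (Welch by default) for inhibitor effects.

    Zero variance in both groups returns p = 1 for equal means and a
    degenerate flag (statistic NaN) for unequal means rather than raising.
    """
    a = np.asarray(control, float)
    b = np.asarray(treated, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two samples per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return TTestResult(0.0, 1.0, "welch" if not equal_var else "pooled")
        return TTestResult(
            float("nan"), 0.0, "welch" if not equal_var else "pooled", degenerate=True
        )
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return TTestResult(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        variant="pooled" if equal_var else "welch",
    )


def permutation_pvalue(
    control: Sequence[float],
    treated: Sequence[float],
    n_perm: int = 20000,
    seed: int = 0,
) -> float:
    """Exact/Monte-Carlo permutation p-value for the mean difference.

    Brute-force reference for :func:`inhibitor_effect_test` on small
    samples; enumerates all splits when feasible.
    """
    a = np.asarray(control, float)
    b = np.asarray(treated, float)
    pooled = np.concatenate([a, b])
    obs = abs(a.mean() - b.mean())
    n = len(a)
    from math import comb as _comb

    total = _comb(len(pooled), n)
    count = 0
    if total <= n_perm:
        hits = 0
        for idx in itertools.combinations(range(len(pooled)), n):
            mask = np.zeros(len(pooled), bool)
            mask[list(idx)] = True
            d = abs(pooled[mask].mean() - pooled[~mask].mean())
            if d >= obs - 1e-12:
                hits += 1
            count += 1
        return hits / count
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        d = abs(perm[:n].mean() - perm[n:].mean())
        if d >= obs - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)
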