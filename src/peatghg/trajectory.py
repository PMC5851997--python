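"""Cumulative emission trajectories, the mineral-soil sink, and scenarios.

A degrading peat class emits at its constant per-area rate until its C
pool is exhausted (linear depletion — emission factors are constant
rates, so cumulative emission is capped at the stock). The drawn-down
quantity is the all-GHG CO2-C-equivalent flux; an alternative
CO2+DOC-only drawdown can be had by passing those rates instead.

The competing mineral-soil sink is a saturating curve reaching its
maximum additional storage S_max (default 24–64 Gt C, midpoint 44)
within 63 years. The exact saturation equation of the source model is
pluggable; the default is exponential saturation calibrated so that
99% of S_max is reached at the horizon.

The equivalence point is the year at which cumulative peat emissions
overtake the cumulative mineral sink; the future-expansion scenario
grows the degraded area along a Michaelis–Menten schedule toward an
asymptotic doubling.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .uncertainty import Range

LAYERS = ("min", "mean", "max")


@dataclass(frozen=True)
class PoolState:
    """A degrading peat class: C pool (Gt C) and annual emission rate.

    ``rate`` is in Gt CO2-C-eq a^-1 (min/mean/max layers share the pool).
    """

    label: str
    pool_gt: float
    rate: Range

    def __post_init__(self) -> None:
        if self.pool_gt < 0:
            raise ValueError(f"{self.label}: pool must be nonnegative")
        self.rate.validate()
        if self.rate.min < 0:
            raise ValueError(f"{self.label}: emission rates must be nonnegative")


@dataclass(frozen=True)
class ScenarioConfig:
    """Michaelis–Menten area-expansion scenario.

    ``multiplier`` is the asymptotic area multiplier (2.0 = doubling of
    the current degraded area); ``half_saturation_years`` is the time at
    which half of the added area has entered.
    """

    multiplier: float = 2.0
    half_saturation_years: float = 60.0

    def __post_init__(self) -> None:
        if self.half_saturation_years <= 0:
            raise ValueError("half-saturation time must be positive")
        if self.multiplier < 1:
            raise ValueError("area multiplier must be >= 1")


@dataclass
class TrajectorySet:
    """Bundle of cumulative series and their equivalence points."""

    time: np.ndarray
    peat: pd.DataFrame
    sink: pd.DataFrame
    equivalence: Range


def _time_axis(horizon: float, dt: float) -> np.ndarray:
    if dt <= 0 or horizon <= 0:
        raise ValueError("horizon and dt must be positive")
    return np.arange(0.0, horizon + dt / 2, dt)


def peat_trajectory(
    pools: Sequence[PoolState], horizon: float, dt: float = 1.0
) -> pd.DataFrame:
    """Cumulative peat emission (Gt C-eq) with per-class pool exhaustion.

    Each class contributes ``min(rate * t, pool)`` per uncertainty
    layer; classes are summed. Columns: ``t, min, mean, max``.
    """
    t = _time_axis(horizon, dt)
    out = {"t": t}
    for layer in LAYERS:
        total = np.zeros_like(t)
        for p in pools:
            total += np.minimum(getattr(p.rate, layer) * t, p.pool_gt)
        out[layer] = total
    return pd.DataFrame(out)


def exponential_saturation(t: np.ndarray, s_max: float, t_seq: float = 63.0) -> np.ndarray:
    """Default sink form: S_max (1 - exp(-kt)), k set so S(t_seq) = 0.99 S_max."""
    k = np.log(100.0) / t_seq
    return s_max * (1.0 - np.exp(-k * t))


def mineral_sink(
    s_max: Range = Range(24.0, 44.0, 64.0),
    horizon: float = 300.0,
    dt: float = 1.0,
    t_seq: float = 63.0,
    form: Callable[[np.ndarray, float], np.ndarray] | None = None,
) -> pd.DataFrame:
    """Cumulative mineral-soil C sink (Gt C), one column per S_max layer.

    ``form(t, s_max)`` may replace the default exponential saturation,
    e.g. with the source model's own equation; it must be nondecreasing,
    0 at t = 0 and reach S_max (within 1%) at ``t_seq``.
    """
    t = _time_axis(horizon, dt)
    s_max.validate()
    if form is None:
        form = lambda tt, sm: exponential_saturation(tt, sm, t_seq)  # noqa: E731
    out = {"t": t}
    for layer in LAYERS:
        series = np.asarray(form(t, getattr(s_max, layer)), dtype=float)
        if np.any(np.diff(series) < -1e-12):
            raise ValueError("sink curve must be nondecreasing")
        out[layer] = series
    return pd.DataFrame(out)


def equivalence_point(peat: np.ndarray, sink: np.ndarray, t: np.ndarray) -> float:
    """First year at which cumulative peat emission overtakes the sink.

    Linearly interpolated between time steps. If the peat series never
    falls below the sink (e.g. a zero sink), the crossing is at t[0];
    if it never catches up within the horizon, returns +inf.
    """
    peat = np.asarray(peat, dtype=float)
    sink = np.asarray(sink, dtype=float)
    t = np.asarray(t, dtype=float)
    if not (peat.shape == sink.shape == t.shape):
        raise ValueError("series must share one time axis")
    diff = peat - sink
    if np.all(diff >= 0):
        return float(t[0])
    below = diff < 0
    # first index where diff turns nonnegative after having been negative
    candidates = np.nonzero(below[:-1] & (diff[1:] >= 0))[0]
    if candidates.size == 0:
        return float("inf")
    i = int(candidates[0])
    d0, d1 = diff[i], diff[i + 1]
    if d1 == d0:
        return float(t[i + 1])
    frac = -d0 / (d1 - d0)
    return float(t[i] + frac * (t[i + 1] - t[i]))


def equivalence_range(
    peat: pd.DataFrame, sink: pd.DataFrame, pairing: str = "opposed"
) -> Range:
    """Equivalence-point triple across uncertainty layers.

    ``opposed`` (default) pairs the extremes conservatively: the
    earliest point from maximum emissions against the smallest sink,
    the latest from minimum emissions against the largest sink.
    ``matched`` pairs like with like.
    """
    t = peat["t"].to_numpy()
    if not np.array_equal(t, sink["t"].to_numpy()):
        raise ValueError("peat and sink series must share one time axis")
    if pairing == "opposed":
        pairs = {"min": ("max", "min"), "mean": ("mean", "mean"), "max": ("min", "max")}
    elif pairing == "matched":
        pairs = {layer: (layer, layer) for layer in LAYERS}
    else:
        raise ValueError(f"unknown pairing {pairing!r}")
    vals = {
        layer: equivalence_point(peat[pl].to_numpy(), sink[sl].to_numpy(), t)
        for layer, (pl, sl) in pairs.items()
    }
    return Range(vals["min"], vals["mean"], vals["max"])


def mm_expansion(t: float | np.ndarray, config: ScenarioConfig = ScenarioConfig()) -> float | np.ndarray:
    """Degraded-area multiplier at time t under the expansion scenario.

    ``1 + (m - 1) t / (t + K)``: starts at 1, passes halfway to the
    asymptote m at t = K, approaches m as t grows.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be nonnegative")
    m, k = config.multiplier, config.half_saturation_years
    out = 1.0 + (m - 1.0) * t_arr / (t_arr + k)
    return float(out) if np.isscalar(t) else out


def scenario_trajectory(
    pools: Sequence[PoolState],
    horizon: float,
    dt: float = 1.0,
    config: ScenarioConfig = ScenarioConfig(),
) -> pd.DataFrame:
    """Cumulative emission when the degraded area grows along the MM curve.

    Newly degraded area enters as vintages carrying pools and rates
    proportional to the added area fraction; each vintage depletes its
    own pool at the class rate (all vintages of one class share the
    exhaustion time pool/rate). The asymptotic cumulative release is
    ``multiplier x sum(pools)`` per layer.
    """
    if dt > config.half_saturation_years / 10:
        warnings.warn(
            "time step too coarse to resolve the expansion half-saturation; "
            f"dt={dt} > K/10={config.half_saturation_years / 10}",
            stacklevel=2,
        )
    t = _time_axis(horizon, dt)
    mult = mm_expansion(t, config)
    d_mass = np.diff(mult)  # area fraction added within each step
    s_mid = (t[:-1] + t[1:]) / 2.0  # vintage entry at mid-step
    out = {"t": t}
    for layer in LAYERS:
        total = np.zeros_like(t)
        for p in pools:
            rate = getattr(p.rate, layer)
            total += np.minimum(rate * t, p.pool_gt)  # baseline vintage
            if p.pool_gt == 0 or rate == 0 or config.multiplier == 1.0:
                continue
            t_exhaust = p.pool_gt / rate
            # fraction of each vintage's pool emitted by time t
            frac = np.clip((t[:, None] - s_mid[None, :]) / t_exhaust, 0.0, 1.0)
            total += p.pool_gt * (frac @ d_mass)
        out[layer] = total
    return pd.DataFrame(out)


def scenario_asymptote(pools: Sequence[PoolState], config: ScenarioConfig = ScenarioConfig()) -> float:
    """Theoretical maximum cumulative release (Gt C) under the scenario."""
    return config.multiplier * sum(p.pool_gt for p in pools)


def annualized_n_avoidance(total_n_gt: float, equivalence_year: float) -> float:
    """Average avoidable N release (Mt N a^-1) over the equivalence span."""
    if equivalence_year <= 0:
        raise ValueError("equivalence year must be positive")
    return total_n_gt / equivalence_year * 1000.0
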