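"""Stochastic outcome model of the electrostatic Y-junction sorter.

A droplet reaching the junction either takes the wide main channel
(passive default) or, while the pulsing electrode is active, is diverted
into the narrow, higher-resistance "disfavored" collection channel.
Actuated success is a logistic surface in applied potential V (V_RMS),
spacer-oil flow Q (nL/s) and droplet volume; failed actuations are
classified into the three observed failure modes:

* E1 - the pulsed droplet is dragged straight into the main channel
  (low potential, high flow);
* E2 - the droplet enters the disfavored channel but stalls or switches
  back after the pulse (low flow);
* E3 - the droplet merges with the next arrival (low flow, high
  potential, inter-droplet gap shorter than the pulse).

Default coefficients live in ``data/routing_defaults.yaml``; see that file
for the calibration anchors they encode.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .stream_sim import DropletRecord

__all__ = [
    "RoutingModel",
    "FAILURE_MODES",
    "CHANNELS",
    "actuated_success_prob",
    "route_droplet",
    "efficiency_grid",
    "DEFAULT_V_LEVELS",
    "DEFAULT_Q_LEVELS",
]

FAILURE_MODES = ("none", "E1", "E2", "E3")
CHANNELS = ("main", "disfavored", "merged", "burst", "unrouted")

#: Characterisation grid: 7 potential levels spanning the amplifier range
#: (4.6-51.8 V_RMS) x 20 spacer-oil flow levels (5-100 nL/s).
DEFAULT_V_LEVELS = np.linspace(4.6, 51.8, 7)
DEFAULT_Q_LEVELS = np.linspace(5.0, 100.0, 20)


@dataclass(frozen=True)
class RoutingModel:
    """Logistic routing surface plus passive fidelity and regime bounds."""

    beta0: float
    beta_v: float
    beta_q: float
    beta_vq: float
    beta_vol: float = -3.0
    passive_fidelity_60: float = 0.992
    passive_fidelity_80: float = 0.995
    v_low: float = 27.4
    q_low: float = 51.5
    low_flow_knee: float = 10.0

    def __post_init__(self) -> None:
        for name in ("passive_fidelity_60", "passive_fidelity_80"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability")

    @classmethod
    def default(cls) -> "RoutingModel":
        """Load the versioned default coefficients shipped with the package."""
        text = (
            importlib.resources.files("dropsort.data")
            .joinpath("routing_defaults.yaml")
            .read_text()
        )
        raw = yaml.safe_load(text)
        raw.pop("version", None)
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "RoutingModel":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw.pop("version", None)
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"version": 1, **asdict(self)}, fh, sort_keys=False)

    def passive_fidelity(self, flow: float) -> float:
        """Probability an unpulsed droplet takes the main channel at flow Q.

        Linear in flow through the two characterised anchors (60 and
        80 nL/s); below ``low_flow_knee`` the droplet plugs raise the main
        channel's resistance and fidelity degrades linearly toward chance.
        """
        slope = (self.passive_fidelity_80 - self.passive_fidelity_60) / 20.0
        at_knee = self.passive_fidelity_60 + slope * (self.low_flow_knee - 60.0)
        if flow < self.low_flow_knee:
            frac = max(flow, 0.0) / self.low_flow_knee
            return float(np.clip(0.5 + (at_knee - 0.5) * frac, 0.0, 1.0))
        p = self.passive_fidelity_60 + slope * (flow - 60.0)
        return float(np.clip(p, 0.0, 1.0))


def actuated_success_prob(
    voltage: float,
    flow: float,
    volume: float = 1.0,
    model: RoutingModel | None = None,
) -> float:
    """P(diversion into the disfavored channel | pulse) — deterministic."""
    if model is None:
        model = RoutingModel.default()
    if voltage < 0 or flow < 0 or volume < 0:
        raise ValueError("voltage, flow and volume must be >= 0")
    eta = (
        model.beta0
        + model.beta_v * voltage
        + model.beta_q * flow
        + model.beta_vq * voltage * flow
        + model.beta_vol * (volume - 1.0)
    )
    return float(expit(eta))


def _failure_mode(
    voltage: float, flow: float, next_gap: float, pulse_duration: float,
    model: RoutingModel,
) -> str:
    if flow < model.q_low:
        if next_gap < pulse_duration and voltage > model.v_low:
            return "E3"
        return "E2"
    return "E1"


def route_droplet(
    droplet: DropletRecord,
    pulsed: bool,
    voltage: float,
    flow: float,
    next_gap: float,
    model: RoutingModel | None = None,
    rng: np.random.Generator | None = None,
    pulse_duration: float = 0.3,
) -> tuple[str, str]:
    """Draw the routing outcome ``(channel, failure_mode)`` for one droplet.

    Unpulsed droplets take the main channel with the passive fidelity at
    the given flow; a passive misroute into the disfavored channel is a
    false positive but not a failure mode.  Pulsed droplets are diverted
    with ``actuated_success_prob``; on failure the mode follows the regime
    rules (E1 at low potential/high flow, E2 at low flow, E3 substituted
    when the next droplet arrives within the pulse at high potential).
    The outcome is written back onto the record.
    """
    if model is None:
        model = RoutingModel.default()
    if rng is None:
        rng = np.random.default_rng()
    if not pulsed:
        if rng.random() < model.passive_fidelity(flow):
            channel, mode = "main", "none"
        else:
            channel, mode = "disfavored", "none"
    else:
        p = actuated_success_prob(voltage, flow, droplet.volume, model)
        if rng.random() < p:
            channel, mode = "disfavored", "none"
        else:
            mode = _failure_mode(voltage, flow, next_gap, pulse_duration, model)
            channel = "merged" if mode == "E3" else "main"
    droplet.routed_channel = channel
    droplet.failure_mode = mode
    return channel, mode


def efficiency_grid(
    v_levels: np.ndarray | None = None,
    q_levels: np.ndarray | None = None,
    n: int = 10,
    model: RoutingModel | None = None,
    rng: np.random.Generator | int | None = None,
    volume: float = 1.0,
) -> pd.DataFrame:
    """Simulate the two-factor sorter characterisation experiment.

    For every (potential, flow) cell, ``n`` independent sorting attempts
    are made and successes counted, i.e. successes ~ Binomial(n, P) with P
    the actuated success probability.  Returns a tidy table with columns
    ``v_rms, q_nl_s, successes, n`` (one row per cell, 140 rows for the
    default 7 x 20 grid).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if v_levels is None:
        v_levels = DEFAULT_V_LEVELS
    if q_levels is None:
        q_levels = DEFAULT_Q_LEVELS
    if model is None:
        model = RoutingModel.default()
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    rows = []
    for v in np.asarray(v_levels, dtype=float):
        for q in np.asarray(q_levels, dtype=float):
            p = actuated_success_prob(v, q, volume, model)
            rows.append((v, q, int(rng.binomial(n, p)), n))
    return pd.DataFrame(rows, columns=["v_rms", "q_nl_s", "successes", "n"])
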