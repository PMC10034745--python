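"""Quench-flow fluidics design math.

The labeling time of a continuous quench-flow HDX instrument is the transit
time of the mixed sample through a calibrated delay loop between the
labeling (D2O) mixer and the quench mixer: t = V_loop / F_total.  Six loops
with 1.5-2x volume steps, combined with a continuously variable total flow
between a minimum (set by the turbulence floor) and a maximum (set by
syringe-drive limits), give gap-free coverage of labeling times.  Beyond
the longest continuous-mode time the instrument parks the labeled bolus in
a loop, waits, and pushes it into the quench mixer (stop-flow mode).

Fast mixing requires turbulent flow through both mixers, i.e. a Reynolds
number above ~2000:

    LV = F / (pi (d/2)^2)        (linear velocity, mm/s, F in uL/s = mm^3/s)
    Re = LV d / kv               (kv = kinematic viscosity, mm^2/s)

Loop volumes are calibrated by tracer dilution: a loop pre-filled with
tracer stock is flushed with ``delivered_volume`` of solvent and the
collected concentration gives V_loop = DV * C_collected / C_stock.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

RE_TURBULENT = 2000.0


def reynolds(flow: float, d: float = 0.733, kv: float = 1.0) -> float:
    """Reynolds number for volumetric flow ``flow`` (uL/s) through tubing of
    diameter ``d`` (mm) with kinematic viscosity ``kv`` (mm^2/s)."""
    if d <= 0 or kv <= 0:
        raise ValueError("tubing diameter and kinematic viscosity must be positive")
    if flow < 0:
        raise ValueError("flow must be >= 0")
    lv = flow / (math.pi * (d / 2.0) ** 2)  # uL/s == mm^3/s -> mm/s
    return lv * d / kv


def loop_volume_from_dilution(
    conc_stock: float, conc_collected: float, delivered_volume: float = 1000.0
) -> float:
    """Loop volume (uL) from tracer dilution, VL = DV * C_collected / C_stock."""
    if delivered_volume <= 0:
        raise ValueError("delivered_volume must be positive")
    if conc_stock <= 0:
        raise ValueError("stock concentration must be positive")
    if not 0 <= conc_collected <= conc_stock:
        raise ValueError(
            "collected concentration must lie in [0, stock] (impossible dilution)"
        )
    return delivered_volume * conc_collected / conc_stock


def default_loop_volumes(
    smallest: float = 135.0, step: float = 1.75, n: int = 6
) -> list[float]:
    """Six delay-loop volumes in a geometric series (1.5-2x steps)."""
    return [smallest * step**i for i in range(n)]


@dataclass(frozen=True)
class InstrumentConfig:
    """Geometry and flow limits of the quench-flow instrument.

    Defaults mirror the validated prototype: 0.733 mm mixer tubing, water
    viscosity at 20 C, total labeling-mixer flow between 1154 uL/s (the
    Re >= 2000 turbulence floor) and 2700 uL/s (syringe-stall limit minus
    10%), 1:1 quench mixing (doubling the flow through the quench mixer),
    preset stop-flow rates of 2400/4800 uL/s, and six delay loops in 1.75x
    volume steps from 135 uL (50 ms floor at maximum flow).
    """

    tubing_diameter: float = 0.733  # mm
    kinematic_viscosity: float = 1.0  # mm^2/s
    loop_volumes: tuple = tuple(default_loop_volumes())  # uL
    max_flow: float = 2700.0  # uL/s, total through labeling mixer
    min_flow: float = 1154.0  # uL/s
    label_mix_ratio: float = 20.0  # sample : D2O = 1 : ratio
    quench_mix_ratio: float = 1.0  # labeled : quench = 1 : ratio
    stopflow_label_flow: float = 2400.0  # uL/s
    stopflow_quench_flow: float = 4800.0  # uL/s, total through quench mixer
    sample_volume: float = 20.0  # uL injected per labeling reaction
    dead_volume: float = 0.0  # uL between mixers outside the loop

    def __post_init__(self) -> None:
        if self.tubing_diameter <= 0:
            raise ValueError("tubing diameter must be positive")
        if self.min_flow >= self.max_flow:
            raise ValueError("min_flow must be below max_flow")
        loops = tuple(float(v) for v in self.loop_volumes)
        object.__setattr__(self, "loop_volumes", loops)
        if any(b <= a for a, b in zip(loops, loops[1:])):
            raise ValueError("loop volumes must be strictly ascending")
        for a, b in zip(loops, loops[1:]):
            if not 1.25 <= b / a <= 2.5:
                raise ValueError(
                    f"loop volume step {b / a:.2f}x outside the allowed "
                    "1.25-2.5x range"
                )
            if not 1.5 <= b / a <= 2.0:
                warnings.warn(
                    f"loop step {b / a:.2f}x outside the 1.5-2x design band; "
                    "labeling-time coverage may have gaps",
                    stacklevel=3,
                )

    @property
    def labeled_bolus_volume(self) -> float:
        """Volume of the labeled sample after the labeling mixer (uL)."""
        return self.sample_volume * (1.0 + self.label_mix_ratio)

    @property
    def min_continuous_time(self) -> float:
        return self.loop_volumes[0] / self.max_flow

    @property
    def max_continuous_time(self) -> float:
        return self.loop_volumes[-1] / self.min_flow

    def reynolds_label(self, flow: float) -> float:
        return reynolds(flow, self.tubing_diameter, self.kinematic_viscosity)

    def reynolds_quench(self, label_flow: float) -> float:
        return reynolds(
            label_flow * (1.0 + self.quench_mix_ratio),
            self.tubing_diameter,
            self.kinematic_viscosity,
        )


@dataclass(frozen=True)
class TimePointPlan:
    """A realizable labeling time point."""

    requested_time: float  # s
    achieved_time: float  # s
    mode: str  # "continuous" | "stop_flow"
    loop_index: int
    loop_volume: float  # uL
    label_flow: float  # uL/s through the labeling mixer
    quench_flow: float  # uL/s through the quench mixer
    re_label: float
    re_quench: float
    delay: float = 0.0  # stopped-flow wait, s

    @property
    def time_error(self) -> float:
        return self.achieved_time - self.requested_time


def plan_time_point(requested: float, cfg: InstrumentConfig | None = None) -> TimePointPlan:
    """Plan loop choice, flow rates and mode for a requested labeling time.

    Continuous mode is used whenever some loop's transit time can match the
    request within the flow limits (smallest feasible loop wins); otherwise
    stop-flow mode parks the bolus in the smallest loop that holds it and
    makes up the remainder with a stopped delay.  Continuous-mode plans are
    guaranteed turbulent (Re >= 2000) in both mixers because the minimum
    flow is set at the turbulence floor.  Achieved times are reported on a
    0.1 ms grid (well inside the 1 ms design resolution).
    """
    cfg = cfg or InstrumentConfig()
    if requested <= 0:
        raise ValueError("requested labeling time must be positive")
    floor = cfg.min_continuous_time
    if requested < floor - 1e-12:
        raise ValueError(
            f"requested time {requested * 1e3:.3f} ms below the instrument floor "
            f"{floor * 1e3:.3f} ms (smallest loop at maximum flow)"
        )

    # continuous mode: smallest loop whose transit time can match the request
    for i, vol in enumerate(cfg.loop_volumes):
        flow = (vol + cfg.dead_volume) / requested
        if cfg.min_flow - 1e-9 <= flow <= cfg.max_flow + 1e-9:
            flow = min(max(flow, cfg.min_flow), cfg.max_flow)
            achieved = round((vol + cfg.dead_volume) / flow, 4)
            return TimePointPlan(
                requested_time=requested,
                achieved_time=achieved,
                mode="continuous",
                loop_index=i,
                loop_volume=vol,
                label_flow=flow,
                quench_flow=flow * (1.0 + cfg.quench_mix_ratio),
                re_label=cfg.reynolds_label(flow),
                re_quench=cfg.reynolds_quench(flow),
            )

    # stop-flow mode: park the bolus, wait, push out
    bolus = cfg.labeled_bolus_volume
    loop_i = next(
        (i for i, v in enumerate(cfg.loop_volumes) if v >= bolus), None
    )
    if loop_i is None:
        raise ValueError(
            f"labeled bolus volume {bolus:.0f} uL exceeds the largest loop "
            f"({cfg.loop_volumes[-1]:.0f} uL); stop-flow mode infeasible"
        )
    vol = cfg.loop_volumes[loop_i]
    transit = (vol / 2.0) / cfg.stopflow_label_flow + (vol / 2.0) / (
        cfg.stopflow_quench_flow / (1.0 + cfg.quench_mix_ratio)
    )
    delay = requested - transit
    if delay < 0:
        raise ValueError(
            f"requested time {requested:.4f} s shorter than the stop-flow "
            f"transit time {transit:.4f} s and not reachable in continuous mode"
        )
    delay = round(delay, 4)
    return TimePointPlan(
        requested_time=requested,
        achieved_time=round(transit + delay, 4),
        mode="stop_flow",
        loop_index=loop_i,
        loop_volume=vol,
        label_flow=cfg.stopflow_label_flow,
        quench_flow=cfg.stopflow_quench_flow,
        re_label=cfg.reynolds_label(cfg.stopflow_label_flow),
        re_quench=reynolds(
            cfg.stopflow_quench_flow, cfg.tubing_diameter, cfg.kinematic_viscosity
        ),
        delay=delay,
    )


def simulate_dnpa(
    k_true: float,
    times,
    noise_cv: float = 0.0,
    seed: int | None = None,
    amplitude: float = 1.0,
) -> np.ndarray:
    """Synthetic chemical-clock decay trace A(t) = A0 exp(-k t) with
    multiplicative Gaussian noise of coefficient of variation ``noise_cv``.

    Emulates the base-catalysed hydrolysis of 2,4-dinitrophenyl acetate
    (DNPA) used to validate millisecond mixer timing; reproducible by seed.
    """
    if k_true <= 0:
        raise ValueError("k_true must be positive")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    t = np.asarray(times, dtype=float)
    clean = amplitude * np.exp(-k_true * t)
    if noise_cv == 0:
        return clean
    rng = np.random.default_rng(seed)
    return clean * (1.0 + noise_cv * rng.standard_normal(t.shape))


def pseudo_first_order_rate(k2: float, conc: float) -> float:
    """Pseudo-first-order rate constant (s^-1) from a second-order rate
    constant ``k2`` (M^-1 s^-1) at catalyst concentration ``conc`` (M)."""
    if k2 <= 0 or conc <= 0:
        raise ValueError("rate constant and concentration must be positive")
    return k2 * conc
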