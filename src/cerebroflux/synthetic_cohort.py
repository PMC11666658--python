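"""Mechanistic synthetic-cohort simulator.

The study whose analysis this package reproduces deposited no animal data, so
analyses are exercised against simulated cohorts that carry the structure the
pipeline assumes:

* a piecewise-linear proximal-MAP skeleton per study arm, through the group
  medians reported at the key timepoints (baseline plateau, haemorrhagic
  nadir, post-occlusion overshoot, late-occlusion level), plus stationary
  AR(1) measurement noise;
* a monoexponential craniospinal pressure-volume law
  ``ICP = p0 * exp(k * (v_balloon + d_cbv))`` driven by an epidural balloon
  volume ramp (elevated-ICP arm only) and by a cerebral-blood-volume deviation
  ``d_cbv``;
* a two-state autoregulation model: with intact autoregulation a MAP rise
  provokes vasoconstriction (CBV falls, ICP falls); with passive vessels CBV
  follows MAP.  The state relaxes toward its target (passive whenever MAP
  leaves the [LLA, ULA] plateau or an impairment interval is forced) with a
  first-order time constant, so the MAP->ICP coupling that pressure-reactivity
  indices measure is produced by the mechanism, not by the noise generator.

The balloon ramp is calibrated by inverting the exponential elastance so that
the noise-free ICP at the moment of occlusion hits the midpoint of the target
band (25-30 mmHg by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

from .experiment_model import (
    AnimalRecord,
    CohortTable,
    Group,
    HemodynamicSample,
    PhaseSchedule,
    ValidationError,
    phase_of,
)

__all__ = [
    "SimulationConfig",
    "CraniospinalState",
    "estimated_blood_volume",
    "bleed_rate",
    "map_skeleton",
    "icp_from_state",
    "cbv_response",
    "calibrate_balloon_ramp",
    "simulate_animal",
    "simulate_cohort",
    "DEFAULT_MAP_KNOTS",
    "DEFAULT_IMPAIRMENT_SCHEDULE",
]

# MAP skeleton knots (time_min, mmHg) per arm.  Up to T90 the knots are the
# published group medians; the T120 plateau and the reperfusion fall during
# balloon deflation are modelling choices (no medians are published there).
DEFAULT_MAP_KNOTS: dict[Group, tuple[tuple[float, float], ...]] = {
    Group.NICPG: ((-90.0, 94.0), (-30.0, 94.0), (0.0, 45.0), (15.0, 125.0),
                  (90.0, 85.0), (120.0, 80.0), (135.0, 55.0)),
    Group.EICPG: ((-90.0, 99.0), (-30.0, 99.0), (0.0, 41.0), (15.0, 163.0),
                  (90.0, 124.0), (120.0, 110.0), (135.0, 60.0)),
}

# Forced-passive intervals (minutes, occlusion-relative).  The elevated-ICP
# arm's mid-occlusion impairment emerges on its own from the MAP skeleton
# exceeding the upper autoregulation limit (~T5-T40); the episodes that the
# MAP limits cannot explain are forced here.
DEFAULT_IMPAIRMENT_SCHEDULE: dict[Group, tuple[tuple[float, float], ...]] = {
    Group.NICPG: ((20.0, 40.0),),
    Group.EICPG: ((60.0, 85.0),),
}


@dataclass
class SimulationConfig:
    """All knobs of the cohort simulator.

    Pressure units are mmHg, volumes ml, times minutes.  ``g_intact`` and
    ``g_passive`` are the CBV gains (ml per mmHg of MAP deviation from
    baseline) of the intact and passive autoregulation states;
    ``ca_recovery_tau`` is the first-order blending time constant between
    them.  ``elastance_k`` is the exponential craniospinal elastance
    coefficient and ``p0`` the baseline ICP scale.  A fixed ``seed`` makes the
    whole cohort reproducible.
    """

    n_per_group: int = 11
    weight_median: float = 47.5
    weight_iqr: tuple[float, float] = (44.0, 52.0)
    map_knots: dict[Group, tuple[tuple[float, float], ...]] = field(
        default_factory=lambda: dict(DEFAULT_MAP_KNOTS)
    )
    map_floor: float = 40.0          # adrenaline rescue floor during bleeding
    noise_sd: float = 4.0            # stationary MAP noise SD
    noise_ar1: float = 0.6           # AR(1) coefficient at 5-min resolution
    map_offset_sd: float = 8.0       # between-animal MAP level spread
    icp_noise_ratio: float = 0.05    # ICP sensor noise SD = ratio * noise_sd
    lla: float = 50.0                # lower limit of autoregulation
    ula: float = 150.0               # upper limit of autoregulation
    g_intact: float = 0.03
    g_passive: float = 0.06
    ca_recovery_tau: float = 5.0
    map_ref_tau: float = 20.0        # adaptation of the vascular MAP reference
    impairment_schedule: dict[Group, tuple[tuple[float, float], ...]] = field(
        default_factory=lambda: dict(DEFAULT_IMPAIRMENT_SCHEDULE)
    )
    p0: float = 17.0
    p0_sd: float = 2.0               # between-animal baseline-ICP spread
    elastance_k: float = 0.12
    balloon_target_icp: tuple[float, float] = (25.0, 30.0)
    bleed_fraction: float = 0.40
    emit_cvp: bool = False
    cvp_const: float = 7.0
    seed: int = 0
    schedule: PhaseSchedule = field(default_factory=PhaseSchedule)

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValidationError(f"n_per_group must be >= 1, got {self.n_per_group}")
        if not 0.0 <= self.bleed_fraction <= 1.0:
            raise ValidationError(f"bleed_fraction must lie in [0, 1], got {self.bleed_fraction}")
        if not self.lla < self.ula:
            raise ValidationError(f"lla must be below ula, got ({self.lla}, {self.ula})")
        if not 0.0 <= self.noise_ar1 < 1.0:
            raise ValidationError(f"noise_ar1 must lie in [0, 1), got {self.noise_ar1}")
        self.map_knots = {Group.parse(g): tuple(map(tuple, k)) for g, k in self.map_knots.items()}
        self.impairment_schedule = {
            Group.parse(g): tuple(map(tuple, iv)) for g, iv in self.impairment_schedule.items()
        }
        for g, knots in self.map_knots.items():
            ts = [t for t, _ in knots]
            if ts != sorted(ts):
                raise ValidationError(f"map_knots for {g.value} must be time-sorted")


@dataclass
class CraniospinalState:
    """Instantaneous craniospinal state of one animal.

    ``ca_weight`` is the continuous autoregulation state: 1 = fully intact,
    0 = fully passive; transitions blend first-order between the two.
    """

    v_balloon: float = 0.0
    d_cbv: float = 0.0
    ca_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.v_balloon < 0:
            raise ValidationError(f"v_balloon must be >= 0, got {self.v_balloon}")
        if not 0.0 <= self.ca_weight <= 1.0:
            raise ValidationError(f"ca_weight must lie in [0, 1], got {self.ca_weight}")


def estimated_blood_volume(weight: float) -> float:
    """Estimated blood volume in litres: 8% of body weight (kg)."""
    if weight <= 0:
        raise ValidationError(f"weight must be positive, got {weight}")
    return 0.08 * weight


def bleed_rate(weight: float, bleed_fraction: float = 0.40) -> float:
    """Controlled-haemorrhage drainage speed in ml/min.

    A fraction of the estimated blood volume is drained continuously over the
    30-minute bleeding phase; ``bleed_fraction=1.0`` recovers the plain
    EBV/30 formula.
    """
    if not 0.0 < bleed_fraction <= 1.0:
        raise ValidationError(f"bleed_fraction must lie in (0, 1], got {bleed_fraction}")
    return bleed_fraction * estimated_blood_volume(weight) * 1000.0 / 30.0


def map_skeleton(group: Group | str, time: float, config: Optional[SimulationConfig] = None) -> float:
    """Noise-free group-level MAP at one timepoint (piecewise-linear knots).

    Constant extrapolation outside the knot range; the adrenaline floor is
    applied during the bleeding phase only.
    """
    config = config or SimulationConfig()
    group = Group.parse(group) if not isinstance(group, Group) else group
    if group not in config.map_knots:
        raise ValidationError(f"no MAP knots configured for group {group.value}")
    knots = config.map_knots[group]
    ts = np.array([t for t, _ in knots])
    vs = np.array([v for _, v in knots])
    value = float(np.interp(time, ts, vs))
    if phase_of(config.schedule, time) == "bleeding":
        value = max(value, config.map_floor)
    return value


def icp_from_state(
    state: CraniospinalState,
    config: Optional[SimulationConfig] = None,
    p0: Optional[float] = None,
) -> float:
    """ICP from the monoexponential pressure-volume law.

    ``ICP = p0 * exp(k * (v_balloon + d_cbv))`` -- strictly increasing in both
    volume terms; equals ``p0`` exactly at zero added volume.
    """
    config = config or SimulationConfig()
    p0 = config.p0 if p0 is None else p0
    return p0 * math.exp(config.elastance_k * (state.v_balloon + state.d_cbv))


def cbv_response(
    map_now: float,
    map_baseline: float,
    ca: CraniospinalState,
    config: Optional[SimulationConfig] = None,
) -> float:
    """New cerebral-blood-volume deviation (ml) for the current MAP.

    Intact vessels constrict when MAP rises (CBV falls: ``-g_intact * dMAP``);
    passive vessels dilate with it (``+g_passive * dMAP``).  The two responses
    are blended by the continuous autoregulation weight carried in ``ca``.
    """
    config = config or SimulationConfig()
    delta = map_now - map_baseline
    w = ca.ca_weight
    return w * (-config.g_intact * delta) + (1.0 - w) * (config.g_passive * delta)


def _ca_target(group: Group, time: float, map_now: float, config: SimulationConfig) -> float:
    """Target autoregulation weight: passive when forced or MAP off-plateau."""
    forced = any(s <= time < e for s, e in config.impairment_schedule.get(group, ()))
    if forced or map_now < config.lla or map_now > config.ula:
        return 0.0
    return 1.0


def _run_cbv(
    times: np.ndarray,
    map_trace: np.ndarray,
    group: Group,
    config: SimulationConfig,
    map_baseline: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Step the autoregulation state over a MAP trace.

    The cerebrovascular response acts on the deviation of MAP from a slowly
    adapting reference (first-order tracking with ``map_ref_tau``), so a
    sustained pressure shift washes out of the CBV deviation over tens of
    minutes while sample-to-sample fluctuations transmit at the full
    state-dependent gain.  This adaptation is what makes the post-occlusion
    ICP rise transient (a peak followed by gradual decline) instead of a
    sustained step.  Returns the d_cbv trajectory and the
    autoregulation-weight trajectory.
    """
    alpha = 1.0 - math.exp(-config.schedule.step / config.ca_recovery_tau)
    alpha_ref = 1.0 - math.exp(-config.schedule.step / config.map_ref_tau)
    # start in the steady state of the first sample, not mid-transition
    w = _ca_target(group, float(times[0]), float(map_trace[0]), config)
    ref = map_baseline
    d_cbv = np.empty_like(map_trace)
    weights = np.empty_like(map_trace)
    state = CraniospinalState()
    for i, (t, m) in enumerate(zip(times, map_trace)):
        target = _ca_target(group, t, m, config)
        w = w + (target - w) * alpha
        state.ca_weight = w
        state.d_cbv = cbv_response(m, ref, state, config)
        d_cbv[i] = state.d_cbv
        weights[i] = w
        ref = ref + (m - ref) * alpha_ref
    return d_cbv, weights


def calibrate_balloon_ramp(
    config: SimulationConfig,
    animal_p0: float,
    group: Group | str = Group.EICPG,
    d_cbv_at_t0: float = 0.0,
) -> Callable[[float], float]:
    """Epidural-balloon volume ramp ``v_balloon(t)`` for one animal.

    The ramp is zero up to the start of bleeding, rises linearly to the final
    volume at occlusion, and is then held constant (the epidural mass stays in
    place).  The final volume comes from inverting the exponential elastance
    so the noise-free ICP at T0 equals the midpoint of the target band;
    ``d_cbv_at_t0`` lets the caller compensate for a known cerebral-blood-
    volume deviation at that moment (the experimental analogue is titrating
    the balloon against the measured ICP).  Normal-ICP animals get an
    identically zero ramp.
    """
    group = Group.parse(group) if not isinstance(group, Group) else group
    if group is Group.NICPG:
        return lambda t: 0.0
    lo, hi = config.balloon_target_icp
    target = 0.5 * (lo + hi)
    if target <= animal_p0 * math.exp(config.elastance_k * d_cbv_at_t0):
        raise ValidationError(
            f"balloon target {target} mmHg is not above the unloaded ICP for "
            f"p0={animal_p0}; a monotone elastance cannot lower pressure"
        )
    v_final = math.log(target / animal_p0) / config.elastance_k - d_cbv_at_t0
    t_start = config.schedule.bleeding_start
    t_end = config.schedule.occlusion_start
    span = t_end - t_start

    def ramp(t: float) -> float:
        if t <= t_start:
            return 0.0
        if t >= t_end:
            return v_final
        return v_final * (t - t_start) / span

    return ramp


def _draw_weight(u: float, config: SimulationConfig) -> float:
    """Quantile draw through the (Q1, median, Q3) anchors, linear tails."""
    q1, q3 = config.weight_iqr
    med = config.weight_median
    qs = [0.0, 0.25, 0.5, 0.75, 1.0]
    vs = [2 * q1 - med, q1, med, q3, 2 * q3 - med]
    return float(np.interp(u, qs, vs))


def _ar1_noise(rng: np.random.Generator, n: int, sd: float, rho: float) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation ``sd``."""
    if sd == 0.0:
        return np.zeros(n)
    e = np.empty(n)
    innov_sd = sd * math.sqrt(1.0 - rho * rho)
    e[0] = rng.normal(0.0, sd)
    for i in range(1, n):
        e[i] = rho * e[i - 1] + rng.normal(0.0, innov_sd)
    return e


def simulate_animal(config: SimulationConfig, group: Group | str, animal_seed: int) -> AnimalRecord:
    """Simulate one animal's full monitoring trace on the 5-min grid.

    Deterministic given ``(config.seed, animal_seed)``.  ``noise_sd=0``
    switches off every stochastic component (measurement noise, the
    between-animal MAP level offset and the baseline-ICP jitter): the MAP
    trace then equals the skeleton exactly and the elevated-ICP arm hits the
    balloon-target midpoint at T0 exactly.
    """
    group = Group.parse(group) if not isinstance(group, Group) else group
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, int(animal_seed)])
    sched = config.schedule
    times = sched.grid()
    n = len(times)

    weight = _draw_weight(rng.uniform(), config)
    stochastic = config.noise_sd > 0
    p0 = float(np.clip(config.p0 + rng.normal(0.0, config.p0_sd), 10.0, 24.0)) \
        if stochastic else config.p0
    offset = rng.normal(0.0, config.map_offset_sd) if stochastic else 0.0

    skeleton = np.array([map_skeleton(group, t, config) for t in times]) + offset
    pmap = skeleton + _ar1_noise(rng, n, config.noise_sd, config.noise_ar1)
    bleeding = np.array([phase_of(sched, t) == "bleeding" for t in times])
    pmap[bleeding] = np.maximum(pmap[bleeding], config.map_floor)

    map_baseline = map_skeleton(group, sched.bleeding_start, config) + offset

    # Calibrate the balloon against the noise-free trajectory, then run the
    # autoregulation state over the noisy MAP.
    d_cbv_clean, _ = _run_cbv(times, skeleton, group, config, map_baseline)
    i_t0 = int(np.argmin(np.abs(times - sched.occlusion_start)))
    ramp = calibrate_balloon_ramp(config, p0, group, d_cbv_at_t0=float(d_cbv_clean[i_t0]))
    d_cbv, _ = _run_cbv(times, pmap, group, config, map_baseline)

    icp_noise = _ar1_noise(rng, n, config.noise_sd * config.icp_noise_ratio, config.noise_ar1)
    state = CraniospinalState()
    samples = []
    for i, t in enumerate(times):
        state.v_balloon = ramp(float(t))
        state.d_cbv = float(d_cbv[i])
        icp = icp_from_state(state, config, p0=p0) + float(icp_noise[i])
        samples.append(
            HemodynamicSample(
                time=float(t),
                pmap=float(pmap[i]),
                icp=float(icp),
                cvp=config.cvp_const if config.emit_cvp else None,
            )
        )
    return AnimalRecord(
        animal_id=f"pig{animal_seed:02d}", group=group, weight_kg=weight, samples=samples
    )


def simulate_cohort(config: Optional[SimulationConfig] = None) -> CohortTable:
    """Simulate the full two-arm cohort (default 11 + 11 animals).

    Normal-ICP animals are numbered first, mirroring the study's pig 1-11 /
    pig 12-22 arrangement.  Fully reproducible under a fixed config seed.
    """
    config = config or SimulationConfig()
    animals = []
    for i in range(config.n_per_group):
        animals.append(simulate_animal(config, Group.NICPG, i + 1))
    for i in range(config.n_per_group):
        animals.append(simulate_animal(config, Group.EICPG, config.n_per_group + i + 1))
    return CohortTable(animals=animals, schedule=config.schedule)
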