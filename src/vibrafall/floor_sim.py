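"""Synthetic floor-vibration scenario generator.

Turns force profiles of six activity types (fall, walk, free jump,
rhythmic jump, bag drop, ball drop) into multi-sensor floor-acceleration
events via a lightweight modal plate model, so the full detection pipeline
can be trained and benchmarked without laboratory data.

The floor is a simply-supported rectangular plate described by its first
``n x n`` closed-form modes.  Each mode is a damped single-degree-of-freedom
oscillator; the acceleration at a sensor is the modal superposition of the
per-mode responses to the point force, computed by discrete convolution
with each mode's sampled unit-impulse response.  The generator is fully
deterministic given its seed.

Two preset scenario designs replicate the laboratory and the expanded
benchmark experiment inventories (520 falls + 1,170 other events at
1,652 Hz with 4 sensors; 1,725 falls + 7,475 daily-activity events).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.fft import irfft, next_fast_len, rfft

from .fall_load import (
    GRAVITY,
    ForceProfile,
    StageSchedule,
    default_body_params,
    fall_force,
)
from .signal_core import ACTIVITY_LABELS, AccelRecord, EventDataset

# ---------------------------------------------------------------------------
# Floor model
# ---------------------------------------------------------------------------


@dataclass
class FloorModel:
    """Simply-supported rectangular plate reduced to its first modes.

    The mode shapes are the closed-form products
    ``phi_pq(x, y) = 2 / sqrt(M) sin(p pi x / a) sin(q pi y / b)``
    (mass-normalised, ``M`` the total plate mass), and the modal
    frequencies follow the plate law
    ``f_pq = f_11 * ((p/a)^2 + (q/b)^2) / ((1/a)^2 + (1/b)^2)``,
    anchored at the configurable fundamental.  Defaults: a 4 m x 5 m bay,
    5 x 5 retained modes, fundamental near 16.7 Hz (a stiff
    concrete-slab floor) and 3 % modal damping on every mode.
    """

    a: float = 4.0
    b: float = 5.0
    f_fundamental: float = 16.7
    zeta: float = 0.03
    n_modes_axis: int = 5
    surface_density: float = 480.0  # kg/m^2 (~0.2 m RC slab)

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("plate dimensions must be positive")
        if self.f_fundamental <= 0:
            raise ValueError("fundamental frequency must be positive")
        if not (0 < self.zeta <= 0.2):
            raise ValueError("modal damping ratio must lie in (0, 0.2]")
        if self.n_modes_axis < 1:
            raise ValueError("need at least one mode")
        self._kernel_cache: dict = {}

    @property
    def mass(self) -> float:
        return self.surface_density * self.a * self.b

    @property
    def modes(self) -> list[tuple[int, int]]:
        pq = [
            (p, q)
            for p in range(1, self.n_modes_axis + 1)
            for q in range(1, self.n_modes_axis + 1)
        ]
        return sorted(pq, key=lambda m: self.mode_frequency(*m))

    def mode_frequency(self, p: int, q: int) -> float:
        base = (1 / self.a) ** 2 + (1 / self.b) ** 2
        return self.f_fundamental * ((p / self.a) ** 2 + (q / self.b) ** 2) / base

    def mode_shapes(self, xy: tuple[float, float]) -> np.ndarray:
        """Mass-normalised mode shapes evaluated at a point, ordered as
        :attr:`modes`."""
        x, y = xy
        if not (0 <= x <= self.a and 0 <= y <= self.b):
            raise ValueError(f"point {xy} outside the {self.a} x {self.b} plate")
        return np.array(
            [
                2.0
                / np.sqrt(self.mass)
                * np.sin(p * np.pi * x / self.a)
                * np.sin(q * np.pi * y / self.b)
                for p, q in self.modes
            ]
        )

    def _kernels(self, fs: float, n: int):
        """Frequency-domain convolution kernels per mode for n-sample records.

        For a unit modal force f(t), the modal displacement is
        ``q = f * h`` with ``h(t) = exp(-z w t) sin(w_d t) / w_d``; the
        modal acceleration follows from the equation of motion as
        ``q'' = f + f * K`` with ``K(t) = -2 z w h'(t) - w^2 h(t)``
        (the sampled second derivative of h away from t = 0).  The cache
        stores ``rfft(K) * dt`` per mode.
        """
        key = (float(fs), int(n))
        cached = self._kernel_cache.get(key)
        if cached is not None:
            return cached
        nfft = next_fast_len(2 * n - 1)
        t = np.arange(n) / fs
        ks = []
        for p, q in self.modes:
            w = 2 * np.pi * self.mode_frequency(p, q)
            z = self.zeta
            wd = w * np.sqrt(1 - z ** 2)
            e = np.exp(-z * w * t)
            h = e * np.sin(wd * t) / wd
            hdot = e * (np.cos(wd * t) - z * w * np.sin(wd * t) / wd)
            K = -2 * z * w * hdot - w ** 2 * h
            ks.append(K)
        K_hat = rfft(np.asarray(ks), n=nfft, axis=1) / fs
        self._kernel_cache[key] = (nfft, K_hat)
        return nfft, K_hat


def floor_response(
    fm: FloorModel,
    fp: ForceProfile,
    source_xy: tuple[float, float],
    sensor_xy: Sequence[tuple[float, float]],
    fs: float | None = None,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    label: str = "unlabeled",
    meta: dict | None = None,
) -> AccelRecord:
    """Acceleration record (g) at the sensors for a point force on the plate.

    The response is the modal superposition of each mode's convolution with
    the force; optional zero-mean Gaussian noise (SD in g) is added per
    sample.  Deterministic given ``rng``.
    """
    if not fm.modes:
        raise ValueError("floor model has no modes")
    if fs is None:
        fs = fp.fs
    F = np.asarray(fp.F, dtype=float)
    n = F.size
    phi_src = fm.mode_shapes(source_xy)
    phi_sen = np.vstack([fm.mode_shapes(s) for s in sensor_xy])  # (n_sensors, n_modes)
    nfft, K_hat = fm._kernels(fs, n)
    F_hat = rfft(F, n=nfft)
    conv = irfft(F_hat[None, :] * K_hat, n=nfft, axis=1)[:, :n]
    qacc = phi_src[:, None] * (F[None, :] + conv)  # (n_modes, n)
    acc = (phi_sen @ qacc).T / GRAVITY  # (n, n_sensors), in g
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        acc = acc + rng.normal(0.0, noise_sd, size=acc.shape)
    return AccelRecord(acc, fs=fs, label=label, meta=dict(meta or {}))


# ---------------------------------------------------------------------------
# Activity force generators
# ---------------------------------------------------------------------------


def _half_sine(t: np.ndarray, t0: float, tau: float, peak: float) -> np.ndarray:
    """Half-sine pulse of duration tau starting at t0 with given peak."""
    out = np.zeros_like(t)
    inside = (t >= t0) & (t <= t0 + tau)
    out[inside] = peak * np.sin(np.pi * (t[inside] - t0) / tau)
    return out


def _landing_pulse(t, t0, mass, v_land, tau):
    """Half-sine landing impulse carrying momentum mass * v_land."""
    peak = np.pi * mass * v_land / (2.0 * tau)
    return _half_sine(t, t0, tau, peak)


def activity_force(
    kind: str,
    params: dict,
    fs: float,
    duration: float,
    rng: np.random.Generator | None = None,
) -> ForceProfile:
    """Vertical floor-force profile for one event of the given activity.

    ``params`` is activity specific:

    * ``fall`` — ``mass_kg``, optional ``height_m`` (1.75), optional
      ``direction`` (``backward``/``forward``; forward applies a damping
      multiplier to the impact stage).  Uses the four-stage fall model with
      the stage schedule scaled to ``duration``.
    * ``walk`` — ``mass_kg``, ``step_rate_hz`` (2.0), ``step_jitter_s``
      (0.05), optional ``n_steps`` (else filled from duration).  Per-step
      support pulse plus a short heel-strike transient.
    * ``free_jump`` — ``mass_kg``, ``n_landings`` (random 2-4), landing
      heights random in ``jump_height_range_m`` (0.1-0.3 m).
    * ``rhythmic_jump`` — ``mass_kg``, ``rate_hz`` (1.5, i.e. 90 bpm),
      ``jitter_s`` (0.0), ``jump_height_m`` (0.05).
    * ``bag_drop`` / ``ball_drop`` — ``mass_kg``, ``drop_height_m``; a
      single impulse with peak proportional to
      ``mass * sqrt(2 g drop_height)``; the ball adds restitution bounces.
    """
    if kind not in ACTIVITY_LABELS:
        raise ValueError(f"unknown activity {kind!r}; expected one of {ACTIVITY_LABELS}")
    if rng is None:
        rng = np.random.default_rng()
    n = int(round(duration * fs)) + 1
    t = np.arange(n) / fs
    F = np.zeros(n)
    g = GRAVITY

    if kind == "fall":
        mass = float(params["mass_kg"])
        height = float(params.get("height_m", 1.75))
        direction = params.get("direction", "backward")
        p = default_body_params(mass_kg=mass, height_m=height)
        if direction == "forward":
            # forward falls bleed more energy through protective contact;
            # modelled as extra impact-stage damping
            mult = float(params.get("forward_damping_multiplier", 1.3))
            p = type(p)(m=p.m, k=p.k, c=tuple(ci * mult for ci in p.c),
                        body_mass=p.body_mass, h=p.h, g=p.g)
        ref = StageSchedule()
        s = duration / ref.t_rest
        sched = StageSchedule(
            t_stand=ref.t_stand * s, t_fall=ref.t_fall * s,
            t_impact=ref.t_impact * s, t_rest=ref.t_rest * s,
        )
        fp = fall_force(p, sched=sched, fs=fs)
        F = fp.F[:n] if fp.F.size >= n else np.pad(fp.F, (0, n - fp.F.size),
                                                   constant_values=fp.F[-1])
    elif kind == "walk":
        mass = float(params["mass_kg"])
        rate = float(params.get("step_rate_hz", 2.0))
        jitter = float(params.get("step_jitter_s", 0.05))
        n_steps = params.get("n_steps")
        if n_steps is None:
            n_steps = max(int(duration * rate) - 1, 0)
        n_steps = int(n_steps)
        for s_i in range(n_steps):
            t0 = (s_i + 0.5) / rate + (rng.normal(0.0, jitter) if jitter > 0 else 0.0)
            t0 = float(np.clip(t0, 0.0, max(duration - 0.05, 0.0)))
            F += _half_sine(t, t0, 0.45, 1.3 * mass * g)  # support phase
            F += _half_sine(t, t0, 0.02, 0.05 * mass * g)  # heel strike
    elif kind == "free_jump":
        mass = float(params["mass_kg"])
        lo, hi = params.get("jump_height_range_m", (0.05, 0.25))
        n_land = int(params.get("n_landings", rng.integers(2, 5)))
        for _ in range(n_land):
            t0 = float(rng.uniform(0.1, max(duration - 0.2, 0.1)))
            v = np.sqrt(2 * g * rng.uniform(lo, hi))
            F += _landing_pulse(t, t0, mass, v, 0.06)
    elif kind == "rhythmic_jump":
        mass = float(params["mass_kg"])
        rate = float(params.get("rate_hz", 1.5))
        jitter = float(params.get("jitter_s", 0.0))
        v = np.sqrt(2 * g * float(params.get("jump_height_m", 0.03)))
        k = 0
        while True:
            t0 = 0.2 + k / rate
            if t0 > duration - 0.1:
                break
            if jitter > 0:
                t0 += float(rng.normal(0.0, jitter))
            F += _landing_pulse(t, t0, mass, v, 0.06)
            k += 1
    elif kind in ("bag_drop", "ball_drop"):
        mass = float(params["mass_kg"])
        h_drop = float(params["drop_height_m"])
        v = np.sqrt(2 * g * h_drop)
        t0 = float(params.get("t_impact_s", 0.3))
        if kind == "bag_drop":
            F += _landing_pulse(t, t0, mass, v, 0.025)  # dead (no-bounce) impact
        else:
            e_rest = float(params.get("restitution", 0.6))
            tb, vb = t0, v
            for _ in range(3):
                F += _landing_pulse(t, tb, mass, vb, 0.015)  # hard impact
                tb = tb + 2 * e_rest * vb / g
                vb = e_rest * vb
                if tb > duration:
                    break
    return ForceProfile(t=t, F=F, meta={"activity": kind, **params})


# ---------------------------------------------------------------------------
# Scenario designs
# ---------------------------------------------------------------------------


@dataclass
class ActivityEntry:
    """One inventory row: how many events of an activity, with which
    parameter alternatives (list-valued parameters are cycled across
    events for a balanced design)."""

    activity: str
    count: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.activity not in ACTIVITY_LABELS:
            raise ValueError(f"unknown activity {self.activity!r} in inventory")
        if self.count < 0:
            raise ValueError("inventory count must be nonnegative")


@dataclass
class ScenarioDesign:
    """Full synthetic-experiment design: inventory, sensors, acquisition."""

    inventory: list[ActivityEntry]
    sensors: list[tuple[float, float]]
    fs: float = 1652.0
    duration: float = 2.0
    noise_sd: float = 0.001  # g
    seed: int | None = None
    amplitude_jitter: float = 0.3  # lognormal sigma on force amplitude
    position_jitter: float = 0.6  # m, SD of excitation-position scatter
    positions: list[tuple[float, float]] = field(
        default_factory=lambda: [(1.3, 1.8), (2.7, 3.2)]
    )
    walk_path: tuple[tuple[float, float], tuple[float, float]] = ((0.6, 0.8), (3.4, 4.2))

    def __post_init__(self) -> None:
        if self.duration * self.fs < 2:
            raise ValueError("duration * fs must be at least 2 samples")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be nonnegative")

    def total_events(self) -> int:
        return sum(e.count for e in self.inventory)


def _expand_alternatives(params: dict, index: int) -> dict:
    """Resolve list-valued parameters by cycling over their cross product."""
    keys = [k for k, v in params.items() if isinstance(v, (list, tuple))
            and k not in ("jump_height_range_m", "positions")]
    out = dict(params)
    if keys:
        sizes = [len(params[k]) for k in keys]
        rem = index
        for k, s in zip(keys, sizes):
            out[k] = params[k][rem % s]
            rem //= s
    return out


def generate_scenario(
    design: ScenarioDesign,
    fm: FloorModel | None = None,
    seed: int | None = None,
) -> EventDataset:
    """Generate one labelled event dataset from a scenario design.

    One record per inventory entry count, in inventory order; parameter
    alternatives are cycled for balance, excitation positions are jittered,
    force amplitudes carry lognormal event-to-event variability, and
    Gaussian sensor noise is added.  Identical ``(design, floor, seed)``
    yield bit-identical datasets.
    """
    if fm is None:
        fm = FloorModel()
    rng = np.random.default_rng(design.seed if seed is None else seed)
    margin = 0.1
    records: list[AccelRecord] = []

    def _jitter_pos(xy):
        x = np.clip(xy[0] + rng.normal(0, design.position_jitter),
                    margin, fm.a - margin)
        y = np.clip(xy[1] + rng.normal(0, design.position_jitter),
                    margin, fm.b - margin)
        return float(x), float(y)

    for entry in design.inventory:
        positions = entry.params.get("positions", design.positions)
        for i in range(entry.count):
            params = _expand_alternatives(
                {k: v for k, v in entry.params.items() if k != "positions"}, i
            )
            amp = float(rng.lognormal(0.0, design.amplitude_jitter)) \
                if design.amplitude_jitter > 0 else 1.0
            meta = {"activity": entry.activity, "index": i, **params}
            if entry.activity == "walk":
                rec = _walk_record(design, fm, params, amp, rng)
            else:
                pos = _jitter_pos(positions[i % len(positions)])
                fp = activity_force(entry.activity, params, design.fs,
                                    design.duration, rng=rng)
                # the floor responds to force deviations from the initial
                # static state (a standing body pre-loads the slab)
                F_dyn = fp.F - fp.F[0]
                fp_dyn = ForceProfile(fp.t, amp * F_dyn, meta=fp.meta)
                meta["position"] = pos
                rec = floor_response(
                    fm, fp_dyn, pos, design.sensors, fs=design.fs,
                    noise_sd=design.noise_sd, rng=rng,
                    label=entry.activity, meta=meta,
                )
            records.append(rec)
    return EventDataset(records=records)


def _walk_record(
    design: ScenarioDesign,
    fm: FloorModel,
    params: dict,
    amp: float,
    rng: np.random.Generator,
) -> AccelRecord:
    """Walking as a moving source: one response per footstep along the path,
    superposed (the plate is linear)."""
    mass = float(params["mass_kg"])
    rate = float(params.get("step_rate_hz", 2.0))
    jitter = float(params.get("step_jitter_s", 0.05))
    n_steps = params.get("n_steps")
    if n_steps is None:
        n_steps = max(int(design.duration * rate) - 1, 0)
    n_steps = int(n_steps)
    n = int(round(design.duration * design.fs)) + 1
    t = np.arange(n) / design.fs
    (x0, y0), (x1, y1) = design.walk_path
    acc = np.zeros((n, len(design.sensors)))
    for s_i in range(n_steps):
        frac = (s_i + 0.5) / max(n_steps, 1)
        pos = (x0 + frac * (x1 - x0), y0 + frac * (y1 - y0))
        t0 = (s_i + 0.5) / rate + (rng.normal(0.0, jitter) if jitter > 0 else 0.0)
        t0 = float(np.clip(t0, 0.0, max(design.duration - 0.05, 0.0)))
        g = GRAVITY
        F = _half_sine(t, t0, 0.45, 1.3 * mass * g) + _half_sine(t, t0, 0.02, 0.05 * mass * g)
        step_fp = ForceProfile(t, amp * F)
        step_rec = floor_response(fm, step_fp, pos, design.sensors,
                                  fs=design.fs, noise_sd=0.0)
        acc += step_rec.channels
    if design.noise_sd > 0:
        acc = acc + rng.normal(0.0, design.noise_sd, size=acc.shape)
    return AccelRecord(acc, fs=design.fs, label="walk",
                       meta={"activity": "walk", "n_steps": n_steps, **params})


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

PRESET_NAMES = ("lab_table1", "benchmark_table8")


def preset_designs(name: str) -> ScenarioDesign:
    """Preset scenario designs replicating the two study inventories.

    ``lab_table1`` — 4 sensors at nominal laboratory coordinates, 1,652 Hz:
    520 falls (75/48 kg dummies, 2 positions, 2 directions), 130 walks,
    260 free jumps, 260 rhythmic jumps (1.5 Hz metronome), 260 bag drops
    (5/10 kg from 0.6 m) and 260 ball drops (0.6 kg from 1.45/2.10 m) —
    1,690 events.

    ``benchmark_table8`` — 1,725 falls (60/70/80 kg) plus 7,475 daily
    activities (bag and ball drops from 1.45/2.10 m, free jumps at
    80/55/85 kg) — 9,200 events.
    """
    if name == "lab_table1":
        inventory = [
            ActivityEntry("fall", 520, {
                "mass_kg": [75.0, 48.0],
                "direction": ["backward", "forward"],
                "height_m": 1.75,
            }),
            ActivityEntry("walk", 130, {"mass_kg": [69.0, 78.0]}),
            ActivityEntry("free_jump", 260, {"mass_kg": [69.0, 78.0]}),
            ActivityEntry("rhythmic_jump", 260, {
                "mass_kg": [69.0, 78.0], "rate_hz": 1.5, "jitter_s": 0.02,
            }),
            ActivityEntry("bag_drop", 260, {
                "mass_kg": [5.0, 10.0], "drop_height_m": 0.6,
            }),
            ActivityEntry("ball_drop", 260, {
                "mass_kg": 0.6, "drop_height_m": [1.45, 2.10],
            }),
        ]
        return ScenarioDesign(
            inventory=inventory,
            sensors=[(0.5, 0.5), (0.5, 4.5), (3.5, 4.5), (2.0, 2.5)],
            fs=1652.0,
            duration=2.0,
            noise_sd=0.001,
            seed=0,
        )
    if name == "benchmark_table8":
        inventory = [
            ActivityEntry("fall", 1725, {
                "mass_kg": [60.0, 70.0, 80.0], "direction": "backward",
            }),
            ActivityEntry("bag_drop", 2492, {
                "mass_kg": 5.0, "drop_height_m": [1.45, 2.10],
            }),
            ActivityEntry("ball_drop", 2492, {
                "mass_kg": 0.6, "drop_height_m": [1.45, 2.10],
            }),
            ActivityEntry("free_jump", 2491, {"mass_kg": [80.0, 55.0, 85.0]}),
        ]
        return ScenarioDesign(
            inventory=inventory,
            sensors=[(0.5, 0.5), (0.5, 4.5), (3.5, 4.5), (2.0, 2.5)],
            fs=1652.0,
            duration=2.0,
            noise_sd=0.001,
            seed=0,
        )
    raise ValueError(f"unknown preset {name!r}; expected one of {PRESET_NAMES}")
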