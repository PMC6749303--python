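"""Vertical floor-force model of an unconscious backward human fall.

The force a falling body exerts on the floor is assembled in four stages:

1. **standing** — static equilibrium, ``F = M g``;
2. **falling** — the body accelerates downward and contact force decays
   along a parabola anchored at ``M g`` at the stage start and reaching
   zero with zero slope at lift-off;
3. **impact** — the supine body hits the floor.  The body is modelled as
   three independent damped single-degree-of-freedom oscillators
   (hip, back, head masses ``m_i`` with stiffness ``k_i`` and damping
   ``c_i``, after the ISO 5982 vertical whole-body impedance idealisation),
   each released with downward velocity ``sqrt(2 g h)`` (free fall of the
   body centre of gravity from standing height ``h``) and initial
   acceleration ``g``.  The floor force is the sum of the per-mass dynamic
   reactions plus the static weight of any mass not carried by the
   oscillators: ``F = sum_i m_i (x''_i + g) + (M - sum_i m_i) g``;
4. **resting** — full floor contact, ``F = M g`` again.

Free vibration of each oscillator, ``m x'' + c x' + k x = 0``, is solved in
closed form for any damping ratio.  The stated initial conditions
``x''(0) = g``, ``x'(0) = sqrt(2 g h)`` over-determine the free-vibration
problem unless the initial displacement is back-solved from the equation of
motion at t = 0, giving ``x(0) = -(m g + c sqrt(2 g h)) / k``; that choice
is adopted here, making both initial conditions hold exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

GRAVITY = 9.81  # m/s^2

#: Reference mass (kg) of the default body parameter set.
_REF_MASS = 75.0

#: Fraction of standing height at which the body centre of gravity sits.
COG_HEIGHT_FRACTION = 0.55


@dataclass
class BodyModelParams:
    """Three-mass damped body model (hip, back, head) for the impact stage.

    ``m`` are the concentrated masses (kg), ``k`` the stiffnesses (N/m) and
    ``c`` the damping coefficients (N*s/m), index order hip, back, head.
    ``body_mass`` is the total mass M; any mass not assigned to the three
    oscillators (``M - sum(m)``) is carried statically.  ``h`` is the height
    of the body centre of gravity when standing (m).
    """

    m: tuple[float, float, float]
    k: tuple[float, float, float]
    c: tuple[float, float, float]
    body_mass: float
    h: float
    g: float = GRAVITY

    def __post_init__(self) -> None:
        if len(self.m) != 3 or len(self.k) != 3 or len(self.c) != 3:
            raise ValueError("m, k, c must each have exactly 3 entries")
        if any(mi <= 0 for mi in self.m) or any(ki <= 0 for ki in self.k):
            raise ValueError("masses and stiffnesses must be positive")
        if any(ci < 0 for ci in self.c):
            raise ValueError("damping coefficients must be nonnegative")
        if self.h <= 0:
            raise ValueError("standing centre-of-gravity height must be positive")
        if sum(self.m) > self.body_mass * (1 + 1e-9):
            raise ValueError("sum of concentrated masses exceeds total body mass")


#: Default body parameter set at the 75 kg reference: mass split
#: hip/back/head ~ 36/44/7 % of body mass, per-DOF natural frequencies
#: 4 / 6 / 12 Hz and damping ratios 0.35 / 0.30 / 0.25 — an ISO-5982-style
#: vertical-impedance idealisation.  Overridable everywhere a
#: :class:`BodyModelParams` is accepted.
def default_body_params(
    mass_kg: float = _REF_MASS, height_m: float = 1.75
) -> BodyModelParams:
    """Default three-mass body parameters scaled proportionally to mass.

    Masses, stiffnesses and damping all scale linearly with ``mass_kg`` so
    that per-DOF natural frequencies and damping ratios stay fixed; the
    centre-of-gravity height is ``0.55 * height_m``.
    """
    if not (30.0 <= mass_kg <= 150.0):
        raise ValueError(f"mass {mass_kg} kg outside the supported range [30, 150]")
    scale = mass_kg / _REF_MASS
    m_ref = (27.0, 33.0, 5.5)  # hip, back, head at 75 kg
    f_n = (4.0, 6.0, 12.0)  # Hz
    zeta = (0.35, 0.30, 0.25)
    m = tuple(scale * mi for mi in m_ref)
    k = tuple(mi * (2 * np.pi * fi) ** 2 for mi, fi in zip(m, f_n))
    c = tuple(2 * zi * np.sqrt(ki * mi) for zi, ki, mi in zip(zeta, k, m))
    return BodyModelParams(
        m=m, k=k, c=c, body_mass=mass_kg, h=COG_HEIGHT_FRACTION * height_m
    )


@dataclass
class StageSchedule:
    """Stage end times (s): standing, falling, impact, resting."""

    t_stand: float = 0.25
    t_fall: float = 0.75
    t_impact: float = 1.75
    t_rest: float = 2.0

    def __post_init__(self) -> None:
        if not (0 < self.t_stand < self.t_fall < self.t_impact <= self.t_rest):
            raise ValueError(
                "stage times must satisfy 0 < t_stand < t_fall < t_impact <= t_rest"
            )


@dataclass
class ForceProfile:
    """A vertical floor-force time series F(t) on a uniform grid."""

    t: np.ndarray
    F: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.t.shape != self.F.shape:
            raise ValueError("time and force arrays must have equal shape")
        if not np.all(np.isfinite(self.F)):
            raise ValueError("force profile contains non-finite values")

    @property
    def fs(self) -> float:
        return 1.0 / (self.t[1] - self.t[0])

    def to_csv(self, path: str | Path) -> None:
        """Export as CSV ``time,force_N``."""
        np.savetxt(
            path,
            np.column_stack([self.t, self.F]),
            delimiter=",",
            header="time,force_N",
            comments="",
            fmt="%.17g",
        )


# ---------------------------------------------------------------------------
# Closed-form free vibration
# ---------------------------------------------------------------------------


def _sdof_free(
    m: float, c: float, k: float, x0: float, v0: float, t: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form m x'' + c x' + k x = 0 with x(0)=x0, x'(0)=v0.

    Handles under-, critically and over-damped regimes; returns (x, v, a).
    """
    omega = np.sqrt(k / m)
    zeta = c / (2.0 * np.sqrt(k * m))
    if zeta < 1.0 - 1e-12:
        od = omega * np.sqrt(1.0 - zeta ** 2)
        A = x0
        B = (v0 + zeta * omega * x0) / od
        e = np.exp(-zeta * omega * t)
        cos, sin = np.cos(od * t), np.sin(od * t)
        x = e * (A * cos + B * sin)
        v = e * ((-zeta * omega * A + od * B) * cos + (-zeta * omega * B - od * A) * sin)
    elif zeta <= 1.0 + 1e-12:
        e = np.exp(-omega * t)
        A = x0
        B = v0 + omega * x0
        x = e * (A + B * t)
        v = e * (B - omega * (A + B * t))
    else:
        s = omega * np.sqrt(zeta ** 2 - 1.0)
        r1, r2 = -zeta * omega + s, -zeta * omega - s
        C1 = (v0 - r2 * x0) / (r1 - r2)
        C2 = x0 - C1
        x = C1 * np.exp(r1 * t) + C2 * np.exp(r2 * t)
        v = C1 * r1 * np.exp(r1 * t) + C2 * r2 * np.exp(r2 * t)
    a = -(c * v + k * x) / m
    return x, v, a


def impact_response(
    p: BodyModelParams, duration: float, fs: float
) -> dict[str, np.ndarray]:
    """Free-vibration response of the three body masses after floor contact.

    Each oscillator starts with downward velocity ``sqrt(2 g h)`` and initial
    displacement ``-(m g + c sqrt(2 g h)) / k`` so that its initial
    acceleration equals ``g`` through the equation of motion.  Returns a dict
    with ``t`` (shape (n,)) and ``x``, ``v``, ``a`` (shape (3, n)).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if fs <= 0:
        raise ValueError("fs must be positive")
    n = int(round(duration * fs)) + 1
    t = np.arange(n) / fs
    v0 = np.sqrt(2.0 * p.g * p.h)
    x = np.empty((3, n))
    v = np.empty((3, n))
    a = np.empty((3, n))
    for i in range(3):
        x0 = -(p.m[i] * p.g + p.c[i] * v0) / p.k[i]
        x[i], v[i], a[i] = _sdof_free(p.m[i], p.c[i], p.k[i], x0, v0, t)
    return {"t": t, "x": x, "v": v, "a": a}


# ---------------------------------------------------------------------------
# Four-stage force assembly
# ---------------------------------------------------------------------------


def fall_force(
    p: BodyModelParams, sched: StageSchedule | None = None, fs: float = 1652.0
) -> ForceProfile:
    """Assemble the four-stage floor-force profile F(t) on [0, t_rest].

    Standing and resting stages carry the static weight ``M g``; the falling
    stage is the parabola ``M g ((t_fall - t)/(t_fall - t_stand))^2`` (value
    ``M g`` at the stage start, zero value and slope at lift-off); the
    impact stage sums the dynamic reactions of the three body oscillators
    plus the static weight of the non-modelled mass.  The jump at impact
    onset is physical (shock); F is continuous everywhere else.
    """
    if sched is None:
        sched = StageSchedule()
    n = int(round(sched.t_rest * fs)) + 1
    t = np.arange(n) / fs
    M, g = p.body_mass, p.g
    F = np.full(n, M * g)

    falling = (t > sched.t_stand) & (t <= sched.t_fall)
    tau = (sched.t_fall - t[falling]) / (sched.t_fall - sched.t_stand)
    F[falling] = M * g * tau ** 2

    impact = (t > sched.t_fall) & (t < sched.t_impact)
    if impact.any():
        t_rel = t[impact] - sched.t_fall
        v0 = np.sqrt(2.0 * g * p.h)
        m = np.asarray(p.m)
        a_imp = np.empty((3, t_rel.size))
        for i in range(3):
            x0 = -(p.m[i] * g + p.c[i] * v0) / p.k[i]
            _, _, a_imp[i] = _sdof_free(p.m[i], p.c[i], p.k[i], x0, v0, t_rel)
        static_rest = (M - m.sum()) * g
        F[impact] = (m[:, None] * (a_imp + g)).sum(axis=0) + static_rest

    return ForceProfile(
        t=t,
        F=F,
        meta={
            "model": "four_stage_fall",
            "body_mass_kg": M,
            "schedule": (sched.t_stand, sched.t_fall, sched.t_impact, sched.t_rest),
        },
    )


def fall_force_default(
    mass_kg: float, height_m: float = 1.75, fs: float = 1652.0,
    sched: StageSchedule | None = None,
) -> ForceProfile:
    """Four-stage fall force using the default body parameter set.

    The default ISO-5982-style set is scaled proportionally to ``mass_kg``
    (mass range 30-150 kg); the centre-of-gravity height is
    ``0.55 * height_m``.
    """
    p = default_body_params(mass_kg=mass_kg, height_m=height_m)
    return fall_force(p, sched=sched, fs=fs)
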