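"""Explicit finite-difference integration of the coupled growth system.

Forward-Euler in time (default dt = 0.01 days), conservative central
differences in space, no-flux (mirrored ghost) boundaries at the brain-mask
edge.  Radiotherapy fractions are applied at the start of the treatment
day, before the first PDE step of that day; when an imaging day coincides
with an RT day the snapshot is taken first (pre-fraction imaging).

Auxiliary fields are refreshed on a cadence: the carrying capacity every
step (cheap), the distance-to-periphery field every ``distance_refresh_steps``
steps and at every output/event boundary, and the elasticity solve whenever
the tumor field has moved by more than ``mech_refresh_dphi`` anywhere or at
least once per simulated day.  The elasticity solve is skipped entirely when
``lambda1 == 0`` since stress then has no effect on the dynamics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .grids import (CapacityState, DistanceField, Grid3D,
                    compute_distance_to_periphery, update_carrying_capacity)
from .mechanics import ElasticitySolver, MechanicalParams, damp_diffusion, von_mises
from .models import (ModelSpec, ParameterSet, RTState, apply_rt_instantaneous,
                     coupling_field, effective_death, effective_proliferation,
                     rhs_tumor, rhs_vasculature)


@dataclass
class SolverConfig:
    dt: float = 0.01                      # days
    distance_refresh_steps: int = 25
    mech_refresh_dphi: float = 0.01
    mechanics: bool = True
    tumor_extent_threshold: float | None = None  # default 0.5 * theta_min
    overshoot_warn: float = 1e-6
    auto_subdivide: bool = True


@dataclass
class Schedule:
    rt_days: list[tuple[float, float]] = field(default_factory=list)  # (day, Gy)
    output_days: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.rt_days = sorted(self.rt_days)
        self.output_days = sorted(self.output_days)


def check_stability(D_max: float, dt: float, grid: Grid3D) -> tuple[bool, float]:
    """Explicit-diffusion stability criterion; returns (passes, margin).

    Fails when 2 dt D_max (1/dx^2 + 1/dy^2 + 1/dz^2) exceeds 1; the margin
    is 1 minus that factor.
    """
    factor = 2.0 * dt * D_max * (1.0 / grid.dx ** 2 + 1.0 / grid.dy ** 2 + 1.0 / grid.dz ** 2)
    return factor <= 1.0, 1.0 - factor


class Simulation:
    """Mutable integration state for one model/parameter combination."""

    def __init__(self, grid: Grid3D, phi_T: np.ndarray, phi_V: np.ndarray,
                 cap: CapacityState, params: ParameterSet, spec: ModelSpec,
                 mech: MechanicalParams | None = None,
                 config: SolverConfig | None = None, day: float = 0.0):
        self.grid = grid
        self.config = config or SolverConfig()
        self.params = params
        self.spec = spec
        self.mech = mech or MechanicalParams()
        self.day = float(day)
        self.phi_T = np.asarray(phi_T, dtype=float).copy()
        self.phi_V = np.asarray(phi_V, dtype=float).copy()
        self.cap = cap.replace(theta_max=params.theta_max,
                               phi_V_thresh=params.phi_V_thresh)
        self.rt_state = RTState()
        self.sigma_vm = np.zeros(grid.shape)
        self._mech_solver: ElasticitySolver | None = None
        self._phi_T_at_last_solve = None
        self._last_solve_day = -np.inf
        self._step_count = 0
        self._warned = False
        self.d = np.zeros(grid.shape)
        self.refresh_distance()
        self.refresh_capacity()
        self.refresh_mechanics(force=True)

    # ---- cadence-managed auxiliary fields -------------------------------
    @property
    def extent_threshold(self) -> float:
        thr = self.config.tumor_extent_threshold
        return 0.5 * self.cap.theta_min if thr is None else thr

    def refresh_distance(self) -> None:
        mask = (self.phi_T >= self.extent_threshold) & self.grid.brain_mask
        if mask.any():
            self.d = compute_distance_to_periphery(mask, self.grid).d
        else:
            self.d = np.zeros(self.grid.shape)

    def refresh_capacity(self) -> None:
        self.cap.theta_T = update_carrying_capacity(self.phi_V, self.cap)

    def mechanics_active(self) -> bool:
        return self.config.mechanics and self.mech.lambda1 > 0

    def refresh_mechanics(self, force: bool = False) -> None:
        if not self.mechanics_active():
            return
        due = force or (self.day - self._last_solve_day >= 1.0)
        if not due and self._phi_T_at_last_solve is not None:
            due = np.max(np.abs(self.phi_T - self._phi_T_at_last_solve)) > self.config.mech_refresh_dphi
        if not due:
            return
        if self._mech_solver is None:
            self._mech_solver = ElasticitySolver(self.grid, self.mech)
        u = self._mech_solver.solve(self.phi_T)
        self.sigma_vm = von_mises(u, self.mech, self.grid)
        self._phi_T_at_last_solve = self.phi_T.copy()
        self._last_solve_day = self.day

    def diffusivities(self) -> tuple[np.ndarray, np.ndarray]:
        if self.mechanics_active():
            return (damp_diffusion(self.params.D_T0, self.mech.lambda1, self.sigma_vm),
                    damp_diffusion(self.params.D_V0, self.mech.lambda1, self.sigma_vm))
        shape = self.grid.shape
        return (np.full(shape, self.params.D_T0), np.full(shape, self.params.D_V0))

    # ---- radiotherapy ----------------------------------------------------
    def _couplings(self) -> tuple[np.ndarray, np.ndarray]:
        C_T = coupling_field(self.spec, self.phi_T, self.cap.theta_T, self.phi_V,
                             self.cap.theta_V, self.params.alpha1, species="tumor")
        C_V = coupling_field(self.spec, self.phi_T, self.cap.theta_T, self.phi_V,
                             self.cap.theta_V, self.params.alpha1, species="vascular")
        return C_T, C_V

    def apply_rt_fraction(self) -> None:
        """Deliver one fraction (evaluated before the day's first PDE step)."""
        self.refresh_capacity()
        C_T, C_V = self._couplings()
        if self.spec.rtm in (1, 2):
            self.phi_T = apply_rt_instantaneous(self.phi_T, C_T, self.params.SF)
            self.phi_V = apply_rt_instantaneous(self.phi_V, C_V, self.params.SF)
        self.rt_state.deliver()

    def effective_rates(self):
        """(kp_T, kd_T, kp_V, kd_V_rt) fields for the current state."""
        p, n = self.params, self.rt_state.n_fractions
        kp_T = np.broadcast_to(np.asarray(p.kp_T0, dtype=float), self.grid.shape)
        kd_T = 0.0
        kp_V = p.kp_V
        kd_V_rt = 0.0
        if n >= 1 and self.spec.rtm in (2, 3):
            C_T, C_V = self._couplings()
            kp_T = effective_proliferation(p.kp_T0, C_T, p.SF, n)
            kp_V = effective_proliferation(p.kp_V, C_V, p.SF, n)
            if self.spec.rtm == 3:
                kd_T = effective_death(p.kd_T0, C_T, p.SF, n)
                kd_V_rt = effective_death(p.kd_V, C_V, p.SF, n)
        return kp_T, kd_T, kp_V, kd_V_rt

    # ---- time stepping ---------------------------------------------------
    def step(self, dt: float) -> None:
        grid = self.grid
        self.refresh_capacity()
        if self._step_count % self.config.distance_refresh_steps == 0:
            self.refresh_distance()
        self.refresh_mechanics()
        D_T, D_V = self.diffusivities()
        kp_T, kd_T, kp_V, kd_V_rt = self.effective_rates()
        f_T = rhs_tumor(self.phi_T, self.phi_V, self.cap, D_T, kp_T, kd_T,
                        grid.brain_mask, grid.spacing)
        f_V = rhs_vasculature(self.phi_V, self.phi_T, self.cap, D_V, kp_V,
                              self.params.kd_V, self.d, grid.brain_mask,
                              grid.spacing, kd_rt=kd_V_rt)
        self.phi_T = self.phi_T + dt * f_T
        self.phi_V = self.phi_V + dt * f_V
        self._clip()
        self.day += dt
        self._step_count += 1

    def _clip(self) -> None:
        over = max(float(-self.phi_T.min(initial=0.0)), float(self.phi_T.max(initial=0.0) - 1.0),
                   float(-self.phi_V.min(initial=0.0)), float(self.phi_V.max(initial=0.0) - 1.0))
        if over > self.config.overshoot_warn and not self._warned:
            warnings.warn(f"volume fraction overshoot {over:.2e}; clipping to [0, 1]",
                          RuntimeWarning, stacklevel=2)
            self._warned = True
        np.clip(self.phi_T, 0.0, 1.0, out=self.phi_T)
        np.clip(self.phi_V, 0.0, 1.0, out=self.phi_V)
        bad = ~np.isfinite(self.phi_T[self.grid.brain_mask])
        if bad.any() or not np.all(np.isfinite(self.phi_V[self.grid.brain_mask])):
            raise FloatingPointError(
                f"non-finite field at day {self.day:.3f} (step {self._step_count}); "
                "reduce dt or parameter magnitudes")

    def run_until(self, t: float) -> None:
        """Integrate up to day ``t`` with a stability-checked step size."""
        if t <= self.day + 1e-12:
            return
        dt = self.config.dt
        D_max = max(float(self.params.D_T0), float(self.params.D_V0))
        ok, _ = check_stability(D_max, dt, self.grid)
        while not ok:
            if not self.config.auto_subdivide:
                raise RuntimeError("explicit scheme unstable at requested dt")
            dt *= 0.5
            ok, _ = check_stability(D_max, dt, self.grid)
            if dt < 1e-8:
                raise RuntimeError("could not stabilize time step")
        span = t - self.day
        n_steps = max(1, math.ceil(span / dt - 1e-9))
        h = span / n_steps
        for _ in range(n_steps):
            self.step(h)
        self.day = t  # absorb accumulated round-off


@dataclass
class Trajectory:
    """Fields snapshotted at the requested output days."""

    days: list[float]
    phi_T: dict[float, np.ndarray]
    phi_V: dict[float, np.ndarray]
    n_fractions: int
    final: "Simulation"


def simulate(grid: Grid3D, phi_T0: np.ndarray, phi_V0: np.ndarray,
             cap: CapacityState, params: ParameterSet, spec: ModelSpec,
             schedule: Schedule, mech: MechanicalParams | None = None,
             config: SolverConfig | None = None, initial_day: float = 0.0,
             ) -> Trajectory:
    """Integrate the coupled system and return fields at the output days.

    RT fractions scheduled before the initial day are ignored (the initial
    state is a measured snapshot that already reflects them).  On days where
    imaging and RT coincide, the snapshot precedes the fraction.
    """
    if not schedule.output_days:
        raise ValueError("schedule has no output days")
    if min(schedule.output_days) < initial_day - 1e-9:
        raise ValueError("output day precedes the initial state")
    sim = Simulation(grid, phi_T0, phi_V0, cap, params, spec, mech=mech,
                     config=config, day=initial_day)
    t_end = max(schedule.output_days)
    events: list[tuple[float, str]] = [(d, "out") for d in schedule.output_days]
    events += [(d, "rt") for d, _dose in schedule.rt_days
               if initial_day - 1e-9 <= d <= t_end + 1e-9]
    # snapshot-first ordering on coincident days: "out" sorts before "rt"
    events.sort(key=lambda e: (e[0], e[1] != "out"))
    phi_T_out: dict[float, np.ndarray] = {}
    phi_V_out: dict[float, np.ndarray] = {}
    for t, kind in events:
        sim.run_until(t)
        sim.refresh_distance()
        if kind == "out":
            phi_T_out[t] = sim.phi_T.copy()
            phi_V_out[t] = sim.phi_V.copy()
        else:
            sim.apply_rt_fraction()
    return Trajectory(days=list(schedule.output_days), phi_T=phi_T_out,
                      phi_V=phi_V_out, n_fractions=sim.rt_state.n_fractions,
                      final=sim)
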