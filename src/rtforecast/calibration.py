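"""Parameter calibration of a family member against an animal's visit maps.

Each model is fit to the measured tumor/blood volume-fraction maps by
minimizing the residual sum of squares over both fields at every fitted
visit after the first (the first visit initializes the forward solve).
Optimization is a two-phase hybrid: a simulated-annealing global search
over the bounded parameter box (geometric cooling) followed by a local
least-squares polish (bounded trust-region, Levenberg-Marquardt-like,
numerical Jacobian).  Wald-type 95% confidence intervals come from the
Jacobian at the optimum, and forecast ensembles draw parameter sets
uniformly within those intervals.

Two fitting scenarios mirror the study design: scenario 1 calibrates to
all visits (descriptive fit); scenario 2 calibrates to the first half
(ceil) of the visits and forecasts the rest (predictive test).

The tumor proliferation rate is calibrated either as one global scalar or
as a voxel-node field: each axial slice's tumor bounding box is tiled into
3x3 blocks whose corners and center are calibration nodes; the remaining
voxels take the value of their nearest node, which also regularizes the
field spatially.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize, stats

from .grids import AnimalDataset, CapacityState, Grid3D, Visit, assign_capacity_bounds
from .mechanics import MechanicalParams
from .models import ModelSpec, ParameterSet, active_scalar_params
from .solver import Schedule, SolverConfig, simulate

# Hard calibration bounds: every reported estimate is bracketed by a factor
# of at least two.  Rates 1/day, diffusivities mm^2/day.
RATE_BOUNDS = (1e-3, 10.0)
D_BOUNDS = (1e-4, 0.2)
SF_BOUNDS = (0.5, 1.0)
ALPHA_BOUNDS = (0.0, 10.0)

DEFAULT_SA = {"T0": 1.0, "ratio": 0.95, "iters_per_temp": 50,
              "T_min": 1e-3, "step_frac": 0.15}


@dataclass
class KpFieldParameterization:
    """Node positions and nearest-node interpolation for a local kp field."""

    node_indices: np.ndarray        # (n_nodes, 3) voxel coordinates
    assignment: np.ndarray          # per-grid-voxel node id (flattened grid)
    grid_shape: tuple[int, int, int]

    @property
    def n_nodes(self) -> int:
        return len(self.node_indices)

    def expand(self, node_values: np.ndarray) -> np.ndarray:
        """Full-grid field: each voxel takes its assigned node's value."""
        node_values = np.asarray(node_values, dtype=float)
        if node_values.shape != (self.n_nodes,):
            raise ValueError("node value vector has wrong length")
        return node_values[self.assignment].reshape(self.grid_shape)


def build_kp_parameterization(tumor_union_mask: np.ndarray, grid: Grid3D) -> KpFieldParameterization:
    """Node layout for a locally calibrated proliferation field.

    Within each axial slice that contains tumor, the tumor bounding box is
    tiled into 3x3 in-plane blocks anchored at the box corner; the four
    corners and the center of each block that fall on tumor voxels are
    calibration nodes.  Every other voxel (tumor or not) is assigned its
    nearest node in physical (mm) distance, ties broken by the lowest
    linear voxel index of the node.
    """
    mask = np.asarray(tumor_union_mask, dtype=bool)
    if mask.shape != grid.shape:
        raise ValueError("mask shape mismatch")
    if not mask.any():
        raise ValueError("tumor mask is empty")
    node_mask = np.zeros(grid.shape, dtype=bool)
    pattern = {(0, 0), (0, 2), (2, 0), (2, 2), (1, 1)}
    for z in range(grid.nz):
        sl = mask[:, :, z]
        if not sl.any():
            continue
        xs, ys = np.nonzero(sl)
        x0, x1 = xs.min(), xs.max()
        y0, y1 = ys.min(), ys.max()
        for x in range(x0, x1 + 1):
            for y in range(y0, y1 + 1):
                if ((x - x0) % 3, (y - y0) % 3) in pattern and sl[x, y]:
                    node_mask[x, y, z] = True
    if not node_mask.any():
        # degenerate tiny tumor: every tumor voxel becomes a node
        node_mask = mask.copy()
    # nodes ordered by linear index so argmin tie-breaks to the lowest index
    nodes = np.argwhere(node_mask)
    order = np.lexsort((nodes[:, 2], nodes[:, 1], nodes[:, 0]))
    nodes = nodes[order]
    spacing = np.asarray(grid.spacing)
    node_pos = nodes * spacing
    vox = np.indices(grid.shape).reshape(3, -1).T * spacing
    assignment = np.empty(vox.shape[0], dtype=np.int64)
    chunk = 65536
    for start in range(0, vox.shape[0], chunk):
        seg = vox[start:start + chunk]
        d2 = ((seg[:, None, :] - node_pos[None, :, :]) ** 2).sum(axis=2)
        assignment[start:start + chunk] = np.argmin(d2, axis=1)
    return KpFieldParameterization(node_indices=nodes, assignment=assignment,
                                   grid_shape=grid.shape)


@dataclass
class CalibrationOptions:
    """Knobs for the optimizer; defaults follow the stated protocol."""

    sa: dict | None = field(default_factory=lambda: dict(DEFAULT_SA))
    lm: bool = True
    x0: dict | None = None                 # initial values by parameter name
    free: list[str] | None = None          # restrict calibrated scalars
    base: ParameterSet | None = None       # values for fixed parameters
    eval_dilation: int = 0                 # in-plane dilation of each support
    solver_config: SolverConfig | None = None
    mech: MechanicalParams | None = None
    capacity: CapacityState | None = None  # override measured bounds
    lm_ftol: float = 1e-6
    lm_xtol: float = 1e-10
    lm_gtol: float = 1e-10
    # relative step of the CI Jacobian: a secant scale well above machine
    # precision, because the trajectory depends on parameters with small
    # kinks (thresholded distance-field refresh, clipping); a sqrt(eps)
    # step can land on a kink and produce wildly wrong derivatives
    jac_rel_step: float = 1e-3


@dataclass
class CalibrationResult:
    spec: ModelSpec
    params_hat: ParameterSet
    x_hat: np.ndarray
    names: list[str]
    bounds_lo: np.ndarray
    bounds_hi: np.ndarray
    RSS: float
    k: int
    n_obs: int
    ci95: np.ndarray                  # (k, 2)
    jac: np.ndarray | None
    seed: int
    kp_param: KpFieldParameterization | None
    fitted_visit_days: list[float]
    n_evals: int = 0

    def parameter_set(self, x: np.ndarray) -> ParameterSet:
        return _vector_to_params(x, self.names, self.params_hat, self.kp_param)

    def aic_inputs(self) -> tuple[int, int, float]:
        return self.k, self.n_obs, self.RSS


def scenario_visits(dataset: AnimalDataset, scenario: int) -> tuple[list[int], list[int]]:
    """(fitted, held-out) visit indices: scenario 1 fits all visits,
    scenario 2 fits the first ceil(V/2) and forecasts the rest."""
    n = len(dataset.visits)
    if scenario == 1:
        return list(range(n)), []
    if scenario == 2:
        n_fit = math.ceil(n / 2)
        return list(range(n_fit)), list(range(n_fit, n))
    raise ValueError("scenario must be 1 or 2")


def evaluation_support(visits: list[Visit], grid: Grid3D, dilation: int = 2) -> np.ndarray:
    """Union of the measured tumor masks, dilated in-plane, inside the brain."""
    union = np.zeros(grid.shape, dtype=bool)
    for v in visits:
        union |= np.asarray(v.tumor_mask, dtype=bool)
    if dilation > 0:
        structure = np.zeros((3, 3, 1), dtype=bool)
        structure[1, :, 0] = True
        structure[:, 1, 0] = True
        union = ndimage.binary_dilation(union, structure=structure, iterations=dilation)
    return union & grid.brain_mask


def _param_bounds(name: str, cap: CapacityState) -> tuple[float, float]:
    if name in ("kp_T0", "kd_T0", "kp_V", "kd_V"):
        return RATE_BOUNDS
    if name in ("D_T0", "D_V0"):
        return D_BOUNDS
    if name == "SF":
        return SF_BOUNDS
    if name == "alpha1":
        return ALPHA_BOUNDS
    if name == "phi_V_thresh":
        return (1e-3, 0.999 * cap.theta_V)
    if name == "theta_max":
        return (cap.theta_min, 1.0)
    raise KeyError(name)


def _vector_to_params(x: np.ndarray, names: list[str], base: ParameterSet,
                      kp_param: KpFieldParameterization | None) -> ParameterSet:
    kw = {}
    node_values = []
    for name, val in zip(names, x):
        if name.startswith("kp_T0["):
            node_values.append(val)
        else:
            kw[name] = float(val)
    if node_values:
        kw["kp_T0"] = kp_param.expand(np.asarray(node_values))
    return base.replace(**kw)


class _Objective:
    """Residual vector (and RSS) of a trial parameter vector.

    Residuals are evaluated, per fitted visit, over that visit's measured
    tumor mask (optionally dilated in-plane): the measured volume fractions
    only exist within the imaging ROI, and a homogeneous measured support
    keeps the residual noise homoscedastic, which the Wald intervals
    assume.  A fixed support can be supplied instead (``eval_mask``).
    """

    def __init__(self, dataset: AnimalDataset, spec: ModelSpec,
                 fitted: list[int], names: list[str], base: ParameterSet,
                 kp_param, cap: CapacityState,
                 config: SolverConfig, mech: MechanicalParams | None,
                 eval_mask: np.ndarray | None = None, eval_dilation: int = 0):
        self.dataset = dataset
        self.spec = spec
        self.fitted = fitted
        self.names = names
        self.base = base
        self.kp_param = kp_param
        self.cap = cap
        self.config = config
        self.mech = mech
        first = dataset.visits[fitted[0]]
        self.initial_day = first.day
        self.phi_T0 = np.asarray(first.phi_T, dtype=float)
        self.phi_V0 = np.asarray(first.phi_V, dtype=float)
        self.targets = [dataset.visits[i] for i in fitted[1:]]
        self.schedule = Schedule(rt_days=list(dataset.rt_events),
                                 output_days=[v.day for v in self.targets])
        if eval_mask is not None:
            self.masks = [np.asarray(eval_mask, bool)] * len(self.targets)
        else:
            self.masks = [evaluation_support([v], dataset.grid, eval_dilation)
                          for v in self.targets]
        self.n_obs = 2 * int(sum(m.sum() for m in self.masks))
        self.n_evals = 0

    def residuals(self, x: np.ndarray) -> np.ndarray:
        self.n_evals += 1
        params = _vector_to_params(x, self.names, self.base, self.kp_param)
        try:
            traj = simulate(self.dataset.grid, self.phi_T0, self.phi_V0,
                            self.cap, params, self.spec, self.schedule,
                            mech=self.mech, config=self.config,
                            initial_day=self.initial_day)
        except (FloatingPointError, RuntimeError) as exc:
            warnings.warn(f"forward solve failed during calibration: {exc}",
                          RuntimeWarning, stacklevel=2)
            return np.full(self.n_obs, 1e3)
        r = []
        for v, m in zip(self.targets, self.masks):
            r.append(traj.phi_T[v.day][m] - np.asarray(v.phi_T)[m])
            r.append(traj.phi_V[v.day][m] - np.asarray(v.phi_V)[m])
        return np.concatenate(r)

    def rss(self, x: np.ndarray) -> float:
        r = self.residuals(x)
        if np.all(r == 1e3):
            return float("inf")
        return float(r @ r)


def objective_rss(params: ParameterSet, spec: ModelSpec, dataset: AnimalDataset,
                  fitted_visits: list[int], eval_mask: np.ndarray | None = None,
                  config: SolverConfig | None = None,
                  mech: MechanicalParams | None = None,
                  capacity: CapacityState | None = None) -> tuple[float, int]:
    """RSS of one forward solve against the fitted visits; returns (RSS, n_obs)."""
    if len(fitted_visits) < 2:
        raise ValueError("need at least two fitted visits")
    grid = dataset.grid
    visits = [dataset.visits[i] for i in fitted_visits]
    cap = capacity or dataset.capacity or assign_capacity_bounds(visits)
    obj = _Objective(dataset, spec, fitted_visits, [], params, None, cap,
                     config or SolverConfig(), mech, eval_mask=eval_mask)
    return obj.rss(np.empty(0)), obj.n_obs


def _anneal(obj: _Objective, x0: np.ndarray, lo: np.ndarray, hi: np.ndarray,
            sa: dict, rng: np.random.Generator) -> np.ndarray:
    """Simulated annealing over the bounded box with geometric cooling."""
    x = x0.copy()
    f = obj.rss(x)
    best_x, best_f = x.copy(), f
    scale = max(f, 1e-12) if np.isfinite(f) else 1.0
    T = sa["T0"]
    step = sa.get("step_frac", 0.15) * (hi - lo)
    while T > sa["T_min"]:
        for _ in range(sa["iters_per_temp"]):
            prop = np.clip(x + rng.normal(0.0, 1.0, size=x.size) * step, lo, hi)
            fp = obj.rss(prop)
            if fp < f or rng.random() < np.exp(-(fp - f) / (T * scale)):
                x, f = prop, fp
            if f < best_f:
                best_x, best_f = x.copy(), f
        T *= sa["ratio"]
    return best_x


def calibrate(dataset: AnimalDataset, spec: ModelSpec, seed: int = 0,
              scenario: int = 1, options: CalibrationOptions | None = None,
              ) -> CalibrationResult:
    """Fit one family member to a dataset; deterministic given the seed."""
    options = options or CalibrationOptions()
    fitted, _held = scenario_visits(dataset, scenario)
    if len(fitted) < 2:
        raise ValueError("calibration needs at least two fitted visits")
    grid = dataset.grid
    visits = [dataset.visits[i] for i in fitted]
    cap = options.capacity or assign_capacity_bounds(visits)

    # assemble the calibrated-parameter vector
    names: list[str] = []
    kp_param = None
    if spec.kp_mode == "global":
        names.append("kp_T0")
    else:
        union = np.zeros(grid.shape, dtype=bool)
        for v in visits:
            union |= np.asarray(v.tumor_mask, dtype=bool)
        kp_param = build_kp_parameterization(union, grid)
        names.extend(f"kp_T0[{i}]" for i in range(kp_param.n_nodes))
    names.extend(active_scalar_params(spec))
    if options.free is not None:
        keep = set(options.free)
        names = [n for n in names
                 if n in keep or (n.startswith("kp_T0[") and "kp_T0" in keep)]
    base = options.base or ParameterSet(theta_max=cap.theta_max,
                                        phi_V_thresh=cap.phi_V_thresh)
    lo = np.array([_param_bounds(n.split("[")[0], cap)[0] for n in names])
    hi = np.array([_param_bounds(n.split("[")[0], cap)[1] for n in names])

    x0 = 0.5 * (lo + hi)
    if options.x0:
        for i, n in enumerate(names):
            key = n.split("[")[0]
            if n in options.x0:
                x0[i] = options.x0[n]
            elif key in options.x0:
                x0[i] = float(np.ravel(options.x0[key])[0])
    x0 = np.clip(x0, lo, hi)

    config = options.solver_config or SolverConfig()
    obj = _Objective(dataset, spec, fitted, names, base, kp_param, cap,
                     config, options.mech, eval_dilation=options.eval_dilation)
    if obj.n_obs <= len(names) + 1:
        raise ValueError("more parameters than observations; enlarge the data")

    rng = np.random.default_rng(seed)
    x = x0
    if options.sa is not None:
        x = _anneal(obj, x0, lo, hi, options.sa, rng)
    if options.lm:
        res = optimize.least_squares(obj.residuals, x, bounds=(lo, hi),
                                     method="trf", ftol=options.lm_ftol,
                                     xtol=options.lm_xtol, gtol=options.lm_gtol,
                                     x_scale="jac")
        x = res.x
        rss = float(2.0 * res.cost)
    else:
        rss = obj.rss(x)
    jac = _numerical_jacobian(obj.residuals, x, lo, hi,
                              rel_step=options.jac_rel_step)
    params_hat = _vector_to_params(x, names, base, kp_param)
    k = len(names)
    ci = wald_intervals(jac, rss, obj.n_obs, x)
    return CalibrationResult(spec=spec, params_hat=params_hat, x_hat=x,
                             names=names, bounds_lo=lo, bounds_hi=hi,
                             RSS=rss, k=k, n_obs=obj.n_obs, ci95=ci, jac=jac,
                             seed=seed, kp_param=kp_param,
                             fitted_visit_days=[v.day for v in visits],
                             n_evals=obj.n_evals)


def _numerical_jacobian(fun, x, lo, hi, rel_step: float = 1e-3) -> np.ndarray:
    """Central-difference Jacobian at a secant scale.

    The forward trajectory has small kinks as a function of the parameters
    (threshold crossings in the distance-field refresh, clipping), so the
    step must be large enough to average over them; one-sided differences
    are used only when a bound is in the way.
    """
    f0 = fun(x)
    J = np.empty((f0.size, x.size))
    for j in range(x.size):
        h = rel_step * max(abs(x[j]), 1e-3)
        xp, xm = x.copy(), x.copy()
        up_ok = x[j] + h <= hi[j]
        dn_ok = x[j] - h >= lo[j]
        if up_ok and dn_ok:
            xp[j] = x[j] + h
            xm[j] = x[j] - h
            J[:, j] = (fun(xp) - fun(xm)) / (2 * h)
        elif up_ok:
            xp[j] = x[j] + h
            J[:, j] = (fun(xp) - f0) / h
        else:
            xm[j] = x[j] - h
            J[:, j] = (f0 - fun(xm)) / h
    return J


def wald_intervals(jac: np.ndarray, rss: float, n_obs: int, theta: np.ndarray,
                   level: float = 0.95) -> np.ndarray:
    """Linearized (Wald) confidence intervals from the residual Jacobian.

    cov = (J'J)^-1 * RSS/(n-k); rank-deficient directions get unbounded
    intervals rather than an error.
    """
    theta = np.asarray(theta, dtype=float)
    k = theta.size
    dof = n_obs - k
    if dof <= 0:
        raise ValueError("no residual degrees of freedom")
    JTJ = jac.T @ jac
    s2 = rss / dof
    tval = stats.t.ppf(0.5 + level / 2.0, dof)
    try:
        cov = np.linalg.inv(JTJ)
        if np.any(np.diag(cov) < 0) or not np.all(np.isfinite(cov)):
            raise np.linalg.LinAlgError
        se = np.sqrt(np.diag(cov) * s2)
    except np.linalg.LinAlgError:
        # flag null directions as unbounded
        u, s, _ = np.linalg.svd(JTJ)
        tol = s.max() * max(JTJ.shape) * np.finfo(float).eps if s.size else 0.0
        se = np.full(k, np.inf)
        ok = s > tol
        if ok.any():
            cov = (u[:, ok] / s[ok]) @ u[:, ok].T
            diag = np.diag(cov)
            se = np.where(diag >= 0, np.sqrt(np.abs(diag) * s2), np.inf)
            null_space = (np.abs(u[:, ~ok]).sum(axis=1) > 1e-8) if (~ok).any() else np.zeros(k, bool)
            se[null_space] = np.inf
    half = tval * se
    return np.column_stack([theta - half, theta + half])


def confidence_intervals(result: CalibrationResult) -> np.ndarray:
    """Per-parameter 95% intervals of a converged calibration."""
    return wald_intervals(result.jac, result.RSS, result.n_obs, result.x_hat)


def sample_parameters(result: CalibrationResult, count: int = 100,
                      seed: int = 0) -> list[ParameterSet]:
    """Uniform draws inside each parameter's 95% CI, truncated to bounds."""
    rng = np.random.default_rng(seed)
    lo = np.maximum(result.ci95[:, 0], result.bounds_lo)
    hi = np.minimum(result.ci95[:, 1], result.bounds_hi)
    lo = np.where(np.isfinite(lo), lo, result.bounds_lo)
    hi = np.where(np.isfinite(hi), hi, result.bounds_hi)
    hi = np.maximum(hi, lo)
    out = []
    for _ in range(count):
        x = rng.uniform(lo, hi)
        x = np.where(hi > lo, x, lo)
        out.append(result.parameter_set(x))
    return out
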