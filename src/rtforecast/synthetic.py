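"""Virtual-rat cohort generator with known ground truth.

No animal MRI accompanies the method, so this module manufactures datasets
with the statistical structure the analysis assumes: a Gaussian-profile
lesion (peak tumor volume fraction ~0.6, radius ~1 mm) with peripherally
elevated vasculature is integrated forward under a chosen family member and
treatment schedule, snapshotted on the imaging days, and corrupted with
Gaussian noise at SNR 20 (the noise level of the source imaging study).
The seven imaging/treatment schedules of the animal cohort are available
as presets ``animal1`` .. ``animal7`` (doses of 2 or 4 Gy/day map onto
surviving-fraction presets 0.97 / 0.90, consistent with the observed dose
dependence).  Raw MR signal series (inversion recovery, three-b-value
diffusion, DCE time courses) can be synthesized so the measurement-model
fits can be exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .grids import (AnimalDataset, CapacityState, Grid3D, Visit, LABEL_GRAY,
                    LABEL_WHITE, assign_capacity_bounds)
from .imaging import ADC_WATER_37C
from .mechanics import MechanicalParams
from .models import ModelSpec, ParameterSet
from .solver import Schedule, SolverConfig, simulate


def _expand_days(spans: list[tuple[int, int]]) -> list[int]:
    out: list[int] = []
    for a, b in spans:
        out.extend(range(a, b + 1))
    return out


#: Imaging/treatment schedules of the seven-animal cohort.
SCHEDULE_PRESETS: dict[str, dict] = {
    "animal1": {"dose": 2.0, "image_days": [0, 3, 5, 7, 10, 12, 17, 19, 21],
                "rt_days": _expand_days([(3, 7), (10, 14)])},
    "animal2": {"dose": 4.0, "image_days": [0, 3, 5],
                "rt_days": _expand_days([(3, 5)])},
    "animal3": {"dose": 2.0, "image_days": [0, 3, 5, 7, 10, 12],
                "rt_days": _expand_days([(3, 7), (10, 12)])},
    "animal4": {"dose": 2.0, "image_days": [0, 3, 5],
                "rt_days": _expand_days([(3, 6)])},
    "animal5": {"dose": 2.0, "image_days": [0, 3, 5, 7],
                "rt_days": _expand_days([(3, 6)])},
    "animal6": {"dose": 4.0, "image_days": [0, 2, 5, 7, 8, 12, 14, 16, 19],
                "rt_days": _expand_days([(0, 2), (6, 9), (12, 13)])},
    "animal7": {"dose": 4.0, "image_days": [0, 3, 5, 7, 10, 12, 14, 17],
                "rt_days": _expand_days([(3, 7), (10, 14)])},
}

#: Surviving-fraction presets by daily dose (2 Gy -> high survival).
SF_BY_DOSE = {2.0: 0.97, 4.0: 0.90}


@dataclass
class SyntheticTruth:
    """The stated world: generating model, parameters, schedule and noise."""

    generating_spec: ModelSpec
    generating_params: ParameterSet
    visit_days: list[float]
    rt_days: list[tuple[float, float]]          # (day, dose Gy)
    seed: int = 0
    noise_snr: float = 20.0
    lesion_center: tuple[float, float, float] | None = None   # mm
    lesion_radius: float = 1.0                  # mm (Gaussian 2-sigma radius)
    lesion_peak: float = 0.6
    phi_V_background: float = 0.02
    phi_V_rim: float = 0.08
    theta_min: float = 0.15
    theta_V: float = 0.12
    mask_threshold: float | None = None         # default 0.5 * theta_min


def default_grid(nx: int = 32, ny: int = 32, nz: int = 8,
                 dx: float = 0.25, dy: float = 0.25, dz: float = 1.0) -> Grid3D:
    """Scaled-down study grid: ellipsoidal brain mask, white-matter core."""
    x, y, z = np.indices((nx, ny, nz)).astype(float)
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    r2 = ((x - cx) / (0.48 * nx)) ** 2 + ((y - cy) / (0.48 * ny)) ** 2 \
        + ((z - cz) / (0.48 * nz)) ** 2
    brain = r2 <= 1.0
    labels = np.full((nx, ny, nz), LABEL_GRAY, dtype=np.uint8)
    labels[r2 <= 0.25] = LABEL_WHITE
    return Grid3D(nx, ny, nz, dx, dy, dz, brain_mask=brain, tissue_labels=labels)


def default_truth(preset: str, seed: int = 0, spec: ModelSpec | None = None,
                  noise_snr: float = 20.0) -> SyntheticTruth:
    """Truth record for a cohort preset, parameterized near the reported
    selected-model estimates (proliferation ~1.4/day, diffusivities a few
    1e-2 mm^2/day, SF set by the preset's daily dose)."""
    sched = SCHEDULE_PRESETS[preset]
    dose = sched["dose"]
    params = ParameterSet(
        kp_T0=1.40, kd_T0=0.11, D_T0=2.58e-2, D_V0=3.10e-2,
        phi_V_thresh=0.03, theta_max=0.94, kp_V=0.82, kd_V=0.29,
        SF=SF_BY_DOSE[dose], alpha1=4.0,
    )
    spec = spec or ModelSpec(rtm=3, coupling="C3", kp_mode="global")
    return SyntheticTruth(
        generating_spec=spec, generating_params=params,
        visit_days=[float(d) for d in sched["image_days"]],
        rt_days=[(float(d), dose) for d in sched["rt_days"]],
        seed=seed, noise_snr=noise_snr,
    )


def initial_lesion(truth: SyntheticTruth, grid: Grid3D) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-profile tumor with a vascular rim, on the brain mask."""
    x, y, z = np.indices(grid.shape).astype(float)
    if truth.lesion_center is None:
        # anchored on a voxel center so the profile peak is attained
        center = (grid.nx // 2 * grid.dx, grid.ny // 2 * grid.dy,
                  grid.nz // 2 * grid.dz)
    else:
        center = truth.lesion_center
    r = np.sqrt((x * grid.dx - center[0]) ** 2 + (y * grid.dy - center[1]) ** 2
                + (z * grid.dz - center[2]) ** 2)
    sigma = truth.lesion_radius / 2.0
    phi_T = truth.lesion_peak * np.exp(-0.5 * (r / sigma) ** 2)
    phi_T[phi_T < 1e-4] = 0.0
    rim_sigma = 0.35
    phi_V = truth.phi_V_background + truth.phi_V_rim * np.exp(
        -0.5 * ((r - truth.lesion_radius) / rim_sigma) ** 2)
    phi_T = np.where(grid.brain_mask, phi_T, 0.0)
    phi_V = np.where(grid.brain_mask, phi_V, 0.0)
    return phi_T, phi_V


def truth_capacity(truth: SyntheticTruth, grid: Grid3D) -> CapacityState:
    p = truth.generating_params
    return CapacityState(theta_T=np.full(grid.shape, p.theta_max),
                         theta_min=truth.theta_min, theta_max=p.theta_max,
                         theta_V=truth.theta_V, phi_V_thresh=p.phi_V_thresh)


def add_noise(fieldvals: np.ndarray, snr: float, seed: int,
              mask: np.ndarray | None = None,
              support: np.ndarray | None = None,
              sigma: float | None = None) -> np.ndarray:
    """Additive Gaussian noise with sigma = mean in-mask signal / SNR,
    clipped back to [0, 1].  ``snr = inf`` returns the field unchanged.

    ``support`` restricts where noise is applied (default: everywhere).
    Volume-fraction maps are only measured inside their region of interest,
    so the generator perturbs only those voxels; outside the support the
    field is returned untouched.  An explicit ``sigma`` overrides the
    SNR-derived scale (MRI noise is a property of the acquisition, so the
    cohort generator references it to the pre-treatment image once rather
    than re-scaling it to each visit's signal).
    """
    fieldvals = np.asarray(fieldvals, dtype=float)
    if not snr > 0:
        raise ValueError("snr must be positive (or infinite)")
    if np.isinf(snr):
        return fieldvals.copy()
    if sigma is None:
        if mask is None:
            mask = fieldvals > 0
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("empty mask; noise scale undefined")
        sigma = float(fieldvals[mask].mean()) / snr
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, size=fieldvals.shape)
    if support is not None:
        noise = np.where(np.asarray(support, dtype=bool), noise, 0.0)
    return np.clip(fieldvals + noise, 0.0, 1.0)


def generate_virtual_animal(truth: SyntheticTruth, grid: Grid3D,
                            capacity: str = "measured",
                            config: SolverConfig | None = None,
                            mech: MechanicalParams | None = None) -> AnimalDataset:
    """Integrate the generating model and emit a noisy longitudinal dataset.

    ``capacity`` selects whether the dataset's capacity bounds are derived
    from the noisy measured maps (the faithful pipeline) or copied from
    the generator truth (useful for exact-recovery experiments where the
    truth must be a zero-residual point of the calibration objective).
    """
    p = truth.generating_params
    cap = truth_capacity(truth, grid)
    phi_T0, phi_V0 = initial_lesion(truth, grid)
    thr = truth.mask_threshold if truth.mask_threshold is not None else 0.5 * truth.theta_min
    config = config or SolverConfig(tumor_extent_threshold=thr)
    schedule = Schedule(rt_days=list(truth.rt_days),
                        output_days=[float(d) for d in truth.visit_days])
    traj = simulate(grid, phi_T0, phi_V0, cap, p, truth.generating_spec,
                    schedule, mech=mech, config=config)
    visits = []
    rng_seeds = np.random.default_rng(truth.seed).integers(0, 2 ** 31 - 1, size=2 * len(truth.visit_days))
    # acquisition-referenced noise: SNR defined on the first (pre-treatment)
    # visit's in-tumor signal, with the same sigma at every later visit
    day0 = truth.visit_days[0]
    mask0 = (traj.phi_T[day0] >= thr) & grid.brain_mask
    sigma_T = sigma_V = None
    if np.isfinite(truth.noise_snr) and mask0.any():
        sigma_T = float(traj.phi_T[day0][mask0].mean()) / truth.noise_snr
        sigma_V = float(traj.phi_V[day0][mask0].mean()) / truth.noise_snr
    for i, day in enumerate(truth.visit_days):
        clean_T = traj.phi_T[day]
        clean_V = traj.phi_V[day]
        tumor_mask = (clean_T >= thr) & grid.brain_mask
        # cellularity is only measured inside the tumor ROI; perturbing the
        # quiescent background would seed spurious growth everywhere
        noisy_T = add_noise(clean_T, truth.noise_snr, int(rng_seeds[2 * i]),
                            mask=tumor_mask, support=tumor_mask, sigma=sigma_T)
        noisy_V = add_noise(clean_V, truth.noise_snr, int(rng_seeds[2 * i + 1]),
                            mask=tumor_mask, support=tumor_mask, sigma=sigma_V)
        visits.append(Visit(day=day, phi_T=noisy_T, phi_V=noisy_V, tumor_mask=tumor_mask))
    first_rt = min((d for d, _ in truth.rt_days), default=np.inf)
    pre = [v for v in visits if v.day < first_rt] or visits[:1]
    phi_V_pre = float(np.mean([v.phi_V[v.tumor_mask].mean() for v in pre if v.tumor_mask.any()]))
    if capacity == "truth":
        cap_out = truth_capacity(truth, grid)
    elif capacity == "measured":
        cap_out = assign_capacity_bounds(visits)
    else:
        raise ValueError("capacity must be 'measured' or 'truth'")
    return AnimalDataset(grid=grid, visits=visits, rt_events=list(truth.rt_days),
                         capacity=cap_out, phi_V_pretreatment_mean=phi_V_pre,
                         meta={"truth": truth, "noiseless": {d: (traj.phi_T[d], traj.phi_V[d])
                                                             for d in truth.visit_days}})


# ---------------------------------------------------------------------------
# raw MR signal synthesis
# ---------------------------------------------------------------------------

@dataclass
class MRProtocol:
    """Acquisition constants for the synthetic signal generator."""

    TI: np.ndarray = field(default_factory=lambda: np.arange(125.0, 3025.0 + 1, 100.0))
    b: np.ndarray = field(default_factory=lambda: np.array([150.0, 350.0, 800.0]))
    dce_dt: float = 1.0            # s
    dce_n: int = 120               # samples
    dce_baseline: int = 25         # pre-injection volumes
    ADC_w: float = ADC_WATER_37C
    ADC_min: float = 0.3e-3
    T1_base: float = 1500.0        # ms, non-tumor
    T1_tumor: float = 1800.0       # ms at full cellularity
    t1_star_ratio: float = 0.7     # effective-to-true T1 ratio


def biexponential_aif(t: np.ndarray, t0: float, amp: float = 1.0,
                      m1: float = 1.0 / 40.0, m2: float = 1.0 / 4.0) -> np.ndarray:
    """Simple bolus shape: zero before arrival, then a difference of
    exponentials (fast wash-in, slow wash-out)."""
    tau = np.clip(t - t0, 0.0, None)
    aif = amp * (np.exp(-m1 * tau) - np.exp(-m2 * tau))
    aif[t < t0] = 0.0
    return aif


def synthesize_mr_signals(phi_T: np.ndarray, phi_V: np.ndarray,
                          protocol: MRProtocol | None = None, seed: int = 0,
                          snr: float = np.inf) -> dict:
    """Raw MR series consistent with the given volume-fraction maps.

    The diffusion channel inverts the cellularity map (so the ADC fit and
    the affine conversion round-trip to phi_T); the DCE tissue curves are
    phi_V times the arterial input function (so the AUC ratio round-trips
    to phi_V); inversion-recovery curves follow the three-parameter signal
    model with a cellularity-dependent T1 map.  Gaussian noise at ``snr``
    (relative to the mean in-volume signal) is added when finite.
    """
    protocol = protocol or MRProtocol()
    phi_T = np.asarray(phi_T, dtype=float)
    phi_V = np.asarray(phi_V, dtype=float)
    rng = np.random.default_rng(seed)

    out: dict = {"protocol": protocol}
    # diffusion-weighted: mono-exponential decay at the map's ADC
    ADC = protocol.ADC_w - phi_T * (protocol.ADC_w - protocol.ADC_min)
    S_dw = np.exp(-protocol.b.reshape((1,) * phi_T.ndim + (-1,))
                  * ADC[..., None])
    out["ADC"] = ADC
    out["dw_signals"] = S_dw

    # inversion recovery: signed signals; T1 rises with cellularity
    T1 = protocol.T1_base + (protocol.T1_tumor - protocol.T1_base) * phi_T
    T1s = protocol.t1_star_ratio * T1
    A = T1s / T1   # S0 = 1
    B = 1.0 + T1s / T1
    TI = protocol.TI.reshape((1,) * phi_T.ndim + (-1,))
    S_ir = A[..., None] - B[..., None] * np.exp(-TI / T1s[..., None])
    out["T1"] = T1
    out["ir_signals"] = S_ir
    out["TI"] = protocol.TI

    # DCE: concentration-proportional curves, tissue = phi_V * AIF
    t = np.arange(protocol.dce_n) * protocol.dce_dt
    t0 = protocol.dce_baseline * protocol.dce_dt
    aif = biexponential_aif(t, t0)
    tissue = phi_V[..., None] * aif
    out["dce_t"] = t
    out["aif"] = aif
    out["dce_tissue"] = tissue

    if np.isfinite(snr):
        for key in ("dw_signals", "ir_signals", "dce_tissue"):
            sig = out[key]
            sigma = float(np.abs(sig).mean()) / snr
            out[key] = sig + rng.normal(0.0, sigma, size=sig.shape)
    return out
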