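"""The 18-member family of tumor/vasculature radiotherapy-response models.

The base system is a pair of coupled cross-diffusion reaction equations for
the tumor volume fraction phi_T and the blood volume fraction phi_V:

    dphi_T/dt = div( D_T [ (1 - phi_V/theta_TV) grad(phi_T/theta_TV)
                          + (phi_T/theta_TV)   grad(phi_V/theta_TV) ] )
                + kp_T phi_T (1 - phi_T/theta_T)  [- kd_T phi_T]

and the mirrored equation for phi_V, whose logistic growth is weighted by
the distance-to-periphery field d (angiogenesis at the rim) and whose death
term is weighted by (1 - d) (regression in the core).

Radiotherapy enters through three response mechanisms (RTM1: instantaneous
kill by the surviving fraction SF; RTM2: kill plus a cumulative
proliferation slowdown kp = kp0 C SF^n after n fractions; RTM3: slowdown
plus a delayed death rate kd = kd0 (1 - C SF^n)), each spatially modulated
by one of three coupling fields (C1 = phi/theta packing density, C2 =
exp(-alpha1 phi_V/theta_V) vascularity proxy, C3 = 1), and the tumor
proliferation rate is calibrated either as a single global scalar or as a
voxel-node field -- 3 x 3 x 2 = 18 models.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .grids import CapacityState, DistanceField

COUPLINGS = ("C1", "C2", "C3")
RTMS = (1, 2, 3)
KP_MODES = ("local", "global")


@dataclass(frozen=True)
class ModelSpec:
    """One family member: RT mechanism x coupling x kp parameterization."""

    rtm: int
    coupling: str
    kp_mode: str

    def __post_init__(self) -> None:
        if self.rtm not in RTMS:
            raise ValueError(f"rtm must be one of {RTMS}")
        if self.coupling not in COUPLINGS:
            raise ValueError(f"coupling must be one of {COUPLINGS}")
        if self.kp_mode not in KP_MODES:
            raise ValueError(f"kp_mode must be one of {KP_MODES}")

    @property
    def token(self) -> str:
        return f"{self.kp_mode}-{self.coupling}-RTM{self.rtm}"

    @classmethod
    def from_token(cls, token: str) -> "ModelSpec":
        kp_mode, coupling, rtm = token.split("-")
        return cls(rtm=int(rtm.removeprefix("RTM")), coupling=coupling, kp_mode=kp_mode)


def enumerate_models() -> list[ModelSpec]:
    """All 18 members in the canonical order.

    Local-kp members come first (models 1-9), with the RT mechanism as the
    outer loop and the coupling inner, so models 7-9 are the delayed-death
    (RTM3) members; the global-kp block repeats the pattern (models 10-18).
    """
    out = []
    for kp_mode in KP_MODES:
        for rtm in RTMS:
            for coupling in COUPLINGS:
                out.append(ModelSpec(rtm=rtm, coupling=coupling, kp_mode=kp_mode))
    return out


@dataclass
class ParameterSet:
    """All model constants; rates in 1/day, diffusivities in mm^2/day."""

    kp_T0: float | np.ndarray = 1.0
    kd_T0: float = 0.0
    D_T0: float = 0.02
    D_V0: float = 0.02
    phi_V_thresh: float = 0.03
    theta_max: float = 0.9
    kp_V: float = 0.5
    kd_V: float = 0.2
    SF: float = 1.0
    alpha1: float = 1.0

    def __post_init__(self) -> None:
        for name in ("kd_T0", "D_T0", "D_V0", "kp_V", "kd_V"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if np.any(np.asarray(self.kp_T0) < 0):
            raise ValueError("kp_T0 must be nonnegative")
        if not (0.0 <= self.SF <= 1.0):
            raise ValueError("SF must lie in [0, 1]")

    def replace(self, **kw) -> "ParameterSet":
        return replace(self, **kw)


# Scalar parameters that a given spec actually calibrates (kp_T0 handled
# separately because of the local-field mode).
def active_scalar_params(spec: ModelSpec) -> list[str]:
    names = ["D_T0", "D_V0", "phi_V_thresh", "theta_max", "kp_V", "kd_V", "SF"]
    if spec.rtm == 3:
        names.insert(0, "kd_T0")
    if spec.coupling == "C2":
        names.append("alpha1")
    return names


@dataclass
class RTState:
    """Delivered-fraction counter; effective rates are derived on the fly."""

    n_fractions: int = 0

    def deliver(self) -> None:
        self.n_fractions += 1


def coupling_field(spec: ModelSpec, phi_T: np.ndarray, theta_T: np.ndarray,
                   phi_V: np.ndarray, theta_V: float, alpha1: float,
                   species: str = "tumor") -> np.ndarray:
    """Spatial RT-efficacy modulation field C in (0, 1].

    C1 is the packing density of the treated species (phi_T/theta_T for
    tumor, phi_V/theta_V for vasculature), C2 the vascularity/oxygenation
    proxy exp(-alpha1 phi_V/theta_V) (same for both species), C3 is 1.
    """
    if spec.coupling == "C3":
        return np.ones_like(np.asarray(phi_T, dtype=float))
    if spec.coupling == "C2":
        return np.exp(-alpha1 * np.asarray(phi_V, dtype=float) / theta_V)
    # C1
    if species == "tumor":
        theta = np.asarray(theta_T, dtype=float)
        if np.any(theta <= 0):
            raise ValueError("theta_T must be positive for C1 coupling")
        return np.clip(np.asarray(phi_T, dtype=float) / theta, 0.0, 1.0)
    return np.clip(np.asarray(phi_V, dtype=float) / theta_V, 0.0, 1.0)


def apply_rt_instantaneous(phi: np.ndarray, C: np.ndarray, SF: float) -> np.ndarray:
    """Instantaneous post-fraction field: phi_post = phi_pre * (C * SF)."""
    if not (0.0 <= SF <= 1.0):
        raise ValueError("SF must lie in [0, 1]")
    return np.asarray(phi, dtype=float) * (np.asarray(C, dtype=float) * SF)


def effective_proliferation(kp0, C: np.ndarray, SF: float, n: int) -> np.ndarray:
    """kp = kp0 * C * SF^n after n delivered fractions (n >= 1)."""
    if n < 1:
        raise ValueError("effective rates apply only after the first fraction")
    return np.asarray(kp0, dtype=float) * np.asarray(C, dtype=float) * SF ** n


def effective_death(kd0: float, C: np.ndarray, SF: float, n: int) -> np.ndarray:
    """kd = kd0 * (1 - C * SF^n), the delayed-death rate after n fractions."""
    if n < 1:
        raise ValueError("effective rates apply only after the first fraction")
    return kd0 * (1.0 - np.asarray(C, dtype=float) * SF ** n)


def _face_flux_divergence(D: np.ndarray, coefA: np.ndarray, a: np.ndarray,
                          coefB: np.ndarray, b: np.ndarray,
                          mask: np.ndarray, spacing) -> np.ndarray:
    """div( D [coefA grad a + coefB grad b] ) in conservative face form.

    Face diffusivity is the harmonic mean, face coefficients the arithmetic
    mean; faces crossing the mask boundary carry zero flux, so the masked
    sum of the divergence telescopes to zero exactly.
    """
    out = np.zeros_like(a)
    for axis in range(3):
        h = spacing[axis]
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        lo, hi = tuple(lo), tuple(hi)
        valid = mask[lo] & mask[hi]
        Dl, Dh = D[lo], D[hi]
        with np.errstate(divide="ignore", invalid="ignore"):
            Df = np.where(Dl + Dh > 0, 2.0 * Dl * Dh / np.where(Dl + Dh > 0, Dl + Dh, 1.0), 0.0)
        cAf = 0.5 * (coefA[lo] + coefA[hi])
        cBf = 0.5 * (coefB[lo] + coefB[hi])
        flux = Df * (cAf * (a[hi] - a[lo]) + cBf * (b[hi] - b[lo])) / h
        flux = np.where(valid, flux, 0.0)
        div = np.zeros_like(a)
        div[lo] += flux
        div[hi] -= flux
        out += div / h
    out[~mask] = 0.0
    return out


def _check_finite(*arrays) -> None:
    for arr in arrays:
        if not np.all(np.isfinite(arr)):
            raise ValueError("non-finite input field")


def rhs_tumor(phi_T: np.ndarray, phi_V: np.ndarray, cap: CapacityState,
              D_T: np.ndarray, kp_T: np.ndarray, kd_T,
              mask: np.ndarray, spacing) -> np.ndarray:
    """Right-hand side of the tumor equation (cross-diffusion + logistic
    growth, minus the RTM3 death term when ``kd_T`` is nonzero)."""
    phi_T = np.asarray(phi_T, dtype=float)
    phi_V = np.asarray(phi_V, dtype=float)
    _check_finite(phi_T[mask], phi_V[mask])
    theta_TV = cap.theta_TV
    a = phi_T / theta_TV
    b = phi_V / theta_TV
    coefA = 1.0 - phi_V / theta_TV
    coefB = phi_T / theta_TV
    D = np.broadcast_to(np.asarray(D_T, dtype=float), phi_T.shape)
    rhs = _face_flux_divergence(D, coefA, a, coefB, b, mask, spacing)
    growth = np.asarray(kp_T, dtype=float) * phi_T * (1.0 - phi_T / cap.theta_T)
    death = np.asarray(kd_T, dtype=float) * phi_T
    rhs = rhs + np.where(mask, growth - death, 0.0)
    return rhs


def rhs_vasculature(phi_V: np.ndarray, phi_T: np.ndarray, cap: CapacityState,
                    D_V: np.ndarray, kp_V, kd_V, d: DistanceField | np.ndarray,
                    mask: np.ndarray, spacing,
                    kd_rt=0.0) -> np.ndarray:
    """Right-hand side of the vasculature equation.

    Mirrors the tumor cross-diffusion with the species' roles swapped;
    logistic growth is weighted toward the tumor rim by d, untreated
    regression toward the core by (1 - d).  ``kd_rt`` is the additional
    RTM3 radiotherapy death-rate field (zero otherwise).
    """
    phi_T = np.asarray(phi_T, dtype=float)
    phi_V = np.asarray(phi_V, dtype=float)
    _check_finite(phi_T[mask], phi_V[mask])
    dval = d.d if isinstance(d, DistanceField) else np.asarray(d, dtype=float)
    theta_TV = cap.theta_TV
    a = phi_V / theta_TV
    b = phi_T / theta_TV
    coefA = 1.0 - phi_T / theta_TV
    coefB = phi_V / theta_TV
    D = np.broadcast_to(np.asarray(D_V, dtype=float), phi_V.shape)
    rhs = _face_flux_divergence(D, coefA, a, coefB, b, mask, spacing)
    growth = np.asarray(kp_V, dtype=float) * phi_V * (1.0 - phi_V / cap.theta_V) * dval
    death = np.asarray(kd_V, dtype=float) * phi_V * (1.0 - dval)
    rt_death = np.asarray(kd_rt, dtype=float) * phi_V
    rhs = rhs + np.where(mask, growth - death - rt_death, 0.0)
    return rhs
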