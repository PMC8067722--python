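"""Measurement models: MR signal series to the model's observable fields.

Three quantitative MRI channels feed the growth model:

* inversion-recovery series -> T1 map, via the three-parameter fit
  ``S(TI) = A - B exp(-TI/T1*)`` with ``T1 = T1* (B/A - 1)``;
* diffusion-weighted series -> ADC by mono-exponential (log-linear) fit,
  then tumor volume fraction by the affine cellularity map
  ``phi_T = (ADC_w - ADC) / (ADC_w - ADC_min)``;
* dynamic contrast-enhanced time courses -> blood volume fraction as the
  ratio of the tissue area-under-curve to the arterial-input-function AUC
  over the first 60 s after bolus arrival.

The lesion is segmented by 2-cluster intensity k-means inside a bounding
ROI (the higher-mean cluster is the lesion) followed by hole filling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize
from sklearn.cluster import KMeans

#: free-water ADC at 37 C, mm^2/s (configurable; literature value)
ADC_WATER_37C = 3.0e-3


@dataclass
class IRSeries:
    TI: np.ndarray           # inversion times, ms
    S: np.ndarray            # signal per TI (magnitude or signed)
    magnitude: bool = True

    def __post_init__(self) -> None:
        self.TI = np.asarray(self.TI, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        if len(np.unique(self.TI)) < 3:
            raise ValueError("need at least 3 distinct inversion times")


@dataclass
class DWSeries:
    b: np.ndarray            # b-values, s/mm^2
    S: np.ndarray            # signal per b
    ADC_w: float = ADC_WATER_37C
    ADC_min: float = 0.3e-3

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        if len(np.unique(self.b)) < 2:
            raise ValueError("need at least 2 distinct b-values")
        if not self.ADC_min < self.ADC_w:
            raise ValueError("require ADC_min < ADC_w")


@dataclass
class DCESeries:
    t: np.ndarray                 # seconds, common clock
    tissue: np.ndarray            # (..., n_t) concentration-proportional curves
    aif: np.ndarray               # arterial input function
    window: float = 60.0          # integration window after bolus arrival, s
    n_baseline: int = 25          # pre-injection volumes

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.tissue = np.asarray(self.tissue, dtype=float)
        self.aif = np.asarray(self.aif, dtype=float)


def fit_t1_ir(series: IRSeries) -> tuple[float, float]:
    """(T1, S0) from an inversion-recovery curve.

    Magnitude data have their polarity restored (sign flipped at and below
    the minimum-signal TI) before the nonlinear fit.  Degenerate curves
    (no decay, A <= 0, or non-convergence) raise ValueError so callers can
    flag the voxel.
    """
    TI, S = series.TI, series.S.astype(float).copy()
    order = np.argsort(TI)
    TI, S = TI[order], S[order]
    if np.ptp(S) <= 1e-12 * max(1.0, np.abs(S).max()):
        raise ValueError("constant IR signal; T1 not identifiable")

    def model(ti, A, B, T1s):
        return A - B * np.exp(-ti / T1s)

    if series.magnitude:
        # the polarity of the null-point sample is ambiguous: try flipping
        # through and just before the minimum-signal TI, keep the better fit
        i_min = int(np.argmin(np.abs(S)))
        candidates = []
        for flip_to in (i_min, i_min + 1):
            Sc = np.abs(S).copy()
            Sc[:flip_to] *= -1.0
            candidates.append(Sc)
    else:
        candidates = [S]

    best = None
    for Sc in candidates:
        A0 = Sc.max()
        B0 = A0 - Sc.min()
        T1s0 = max(TI[len(TI) // 3], 1.0)
        try:
            popt, _ = optimize.curve_fit(model, TI, Sc, p0=(A0, B0, T1s0),
                                         maxfev=5000)
        except RuntimeError:
            continue
        sse = float(((model(TI, *popt) - Sc) ** 2).sum())
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:
        raise ValueError("IR fit did not converge")
    A, B, T1s = best[1]
    if A <= 0 or T1s <= 0:
        raise ValueError("IR fit returned non-physical parameters")
    T1 = T1s * (B / A - 1.0)
    if T1 <= 0:
        raise ValueError("IR fit returned non-positive T1")
    S0 = A * T1 / T1s  # from A = S0 T1*/T1
    return float(T1), float(S0)


def fit_adc(series: DWSeries) -> float:
    """ADC (mm^2/s) by least squares on ln S vs b; clamped at zero."""
    if np.any(series.S <= 0):
        raise ValueError("nonpositive diffusion-weighted signal")
    slope = np.polyfit(series.b, np.log(series.S), 1)[0]
    return float(max(-slope, 0.0))


def adc_to_tumor_fraction(ADC_map: np.ndarray, ADC_w: float = ADC_WATER_37C,
                          ADC_min: float = 0.3e-3) -> np.ndarray:
    """Affine, order-reversing ADC -> cellularity map, clipped to [0, 1]."""
    if not ADC_min < ADC_w:
        raise ValueError("require ADC_min < ADC_w")
    phi = (ADC_w - np.asarray(ADC_map, dtype=float)) / (ADC_w - ADC_min)
    return np.clip(phi, 0.0, 1.0)


def detect_bolus_arrival(aif: np.ndarray, n_baseline: int) -> int:
    """First index where the AIF exceeds baseline mean + 5 SD."""
    base = aif[:n_baseline]
    thresh = base.mean() + 5.0 * max(base.std(), 1e-12 * max(abs(base.mean()), 1.0))
    above = np.nonzero(aif > thresh)[0]
    above = above[above >= n_baseline]
    if above.size == 0:
        raise ValueError("no bolus arrival detected in AIF")
    return int(above[0])


def _windowed_auc(t: np.ndarray, curve: np.ndarray, t0: float, window: float) -> np.ndarray:
    """Trapezoid AUC of curve(t) over [t0, t0 + window], interpolating the
    exact window endpoint when it falls between samples."""
    t_end = min(t0 + window, t[-1])
    inside = (t >= t0) & (t <= t_end)
    tt = t[inside]
    cc = curve[..., inside]
    if t_end not in tt:
        flat = np.asarray(curve).reshape(-1, t.size)
        c_end = np.array([np.interp(t_end, t, c) for c in flat])
        c_end = c_end.reshape(curve.shape[:-1] + (1,))
        tt = np.append(tt, t_end)
        cc = np.concatenate([cc, c_end], axis=-1)
    return np.trapezoid(cc, tt, axis=-1)


def dce_blood_volume(series: DCESeries) -> np.ndarray:
    """Blood volume fraction: AUC(tissue)/AUC(AIF) over the first 60 s
    after bolus arrival, clipped to [0, 1]."""
    i0 = detect_bolus_arrival(series.aif, series.n_baseline)
    t0 = series.t[i0]
    auc_aif = _windowed_auc(series.t, series.aif, t0, series.window)
    if not auc_aif > 0:
        raise ValueError("zero AIF area under the curve")
    auc_tissue = _windowed_auc(series.t, series.tissue, t0, series.window)
    return np.clip(auc_tissue / auc_aif, 0.0, 1.0)


def segment_tumor(image: np.ndarray, bounding_roi: np.ndarray, seed: int = 0) -> np.ndarray:
    """Two-cluster k-means lesion segmentation inside a bounding ROI.

    The higher-mean intensity cluster is the lesion; interior holes are
    filled.  Deterministic given the seed.
    """
    image = np.asarray(image, dtype=float)
    roi = np.asarray(bounding_roi, dtype=bool)
    vals = image[roi].reshape(-1, 1)
    if vals.size < 2 or np.ptp(vals) <= 1e-12 * max(1.0, np.abs(vals).max()):
        raise ValueError("ROI intensity is uniform; no separable clusters")
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(vals)
    hi = int(np.argmax(km.cluster_centers_.ravel()))
    mask = np.zeros(image.shape, dtype=bool)
    mask[roi] = km.labels_ == hi
    # fill cavities slice-by-slice (lesions span few slices, so a 3D-only
    # fill would leave axially open holes), then any remaining 3D cavity
    if mask.ndim == 3:
        for z in range(mask.shape[2]):
            mask[:, :, z] = ndimage.binary_fill_holes(mask[:, :, z])
    return ndimage.binary_fill_holes(mask)


def segmentation_noise_harness(image: np.ndarray, bounding_roi: np.ndarray,
                               snr: float, n_replicates: int, voxel_volume: float,
                               seed: int = 0) -> dict:
    """Robustness of the segmentation to imaging noise.

    Adds Gaussian noise at the given SNR (sigma = mean ROI signal / SNR) to
    the image, re-segments ``n_replicates`` times, and reports the standard
    error of the segmented volume (mm^3) and the Dice overlap of each
    replicate against the noiseless segmentation.
    """
    rng = np.random.default_rng(seed)
    ref = segment_tumor(image, bounding_roi, seed=seed)
    sigma = float(np.asarray(image)[np.asarray(bounding_roi, bool)].mean()) / snr
    volumes, dices = [], []
    for _ in range(n_replicates):
        noisy = image + rng.normal(0.0, sigma, size=image.shape)
        m = segment_tumor(noisy, bounding_roi, seed=seed)
        volumes.append(m.sum() * voxel_volume)
        inter = np.logical_and(m, ref).sum()
        dices.append(2.0 * inter / max(m.sum() + ref.sum(), 1))
    volumes = np.asarray(volumes)
    return {
        "volume_se": float(volumes.std(ddof=1) / np.sqrt(len(volumes))),
        "volume_mean": float(volumes.mean()),
        "dice": np.asarray(dices),
        "reference_mask": ref,
    }
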