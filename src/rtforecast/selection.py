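"""Corrected-AIC model scoring, Akaike weights, and ensemble averaging.

Each calibrated family member is scored with the small-sample corrected
Akaike Information Criterion

    AIC = 2k + n ln(RSS/n) + 2k(k+1)/(n-k-1),

where k counts calibrated scalars, n the fitted observations, and RSS the
calibration residual.  Weights w_i = exp(-delta_i/2)/sum_j exp(-delta_j/2)
(delta_i = AIC_i - AIC_min) define both the selected model (lowest AIC,
ties broken by fewer parameters, then family order) and the ensemble
average: within each model the 100 sampled-parameter forecasts are
averaged, and the per-model means are combined with the Akaike weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import ModelSpec, enumerate_models


@dataclass
class AICRecord:
    spec: ModelSpec
    k: int
    n_obs: int
    RSS: float
    AIC: float
    delta: float = np.nan
    weight: float = np.nan


def aic(k: int, n_obs: int, RSS: float) -> float:
    """Corrected AIC; requires n_obs > k + 1 for the correction term."""
    if n_obs <= k + 1:
        raise ValueError("AICc undefined: n_obs must exceed k + 1")
    if RSS <= 0:
        raise ValueError("RSS must be positive")
    return 2.0 * k + n_obs * np.log(RSS / n_obs) + 2.0 * k * (k + 1) / (n_obs - k - 1)


def akaike_weights(aics) -> np.ndarray:
    """Normalized Akaike weights; invariant to a common shift of the AICs."""
    aics = np.asarray(aics, dtype=float)
    finite = np.isfinite(aics)
    if not finite.any():
        raise ValueError("need at least one finite AIC")
    delta = aics - aics[finite].min()
    w = np.where(finite, np.exp(-delta / 2.0), 0.0)
    return w / w.sum()


def score_family(records: list[AICRecord]) -> list[AICRecord]:
    """Fill delta and weight fields in place; returns the records."""
    aics = [r.AIC for r in records]
    ws = akaike_weights(aics)
    amin = np.nanmin([a for a in aics if np.isfinite(a)])
    for r, w in zip(records, ws):
        r.delta = r.AIC - amin
        r.weight = float(w)
    return records


def select_model(records: list[AICRecord]) -> ModelSpec:
    """Spec with the lowest AIC; ties -> fewer parameters, then family order."""
    if not records:
        raise ValueError("no records to select from")
    family_order = {s.token: i for i, s in enumerate(enumerate_models())}
    best = min(records, key=lambda r: (r.AIC, r.k, family_order.get(r.spec.token, 99)))
    return best.spec


def ensemble_average(fields: list[list[np.ndarray]], weights) -> np.ndarray:
    """Weighted ensemble of per-model, per-parameter-sample fields.

    ``fields[i][j]`` is the field from model i and parameter sample j; the
    sample dimension is averaged within each model and the model means are
    combined with the supplied weights (which must sum to 1).
    """
    weights = np.asarray(weights, dtype=float)
    if len(fields) != weights.size:
        raise ValueError("one weight per model required")
    if not np.isclose(weights.sum(), 1.0, atol=1e-9):
        raise ValueError("weights must sum to 1")
    out = None
    shape = None
    for w, model_fields in zip(weights, fields):
        if not model_fields:
            raise ValueError("each model needs at least one sampled field")
        mean = np.mean([np.asarray(f, dtype=float) for f in model_fields], axis=0)
        if shape is None:
            shape = mean.shape
            out = np.zeros(shape)
        elif mean.shape != shape:
            raise ValueError("field grids do not match across models")
        out += w * mean
    return out
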