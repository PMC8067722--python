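"""End-to-end orchestration: calibrate the family, score, forecast, evaluate.

``run_pipeline`` executes, for one dataset and scenario: calibration of the
requested family members -> AICc scoring and Akaike weights -> parameter
sampling within the 95% intervals -> forward forecasts for every sampled
set -> selected-model and ensemble metric reports -> rank-sum comparison
of the two.  All randomness descends from a single root seed recorded in
the output manifest; every stage writes plain CSV/JSON artifacts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import (CalibrationOptions, CalibrationResult, calibrate,
                          sample_parameters, scenario_visits)
from .grids import AnimalDataset, assign_capacity_bounds
from .mechanics import MechanicalParams
from .metrics import (MetricReport, compare_selected_vs_ensemble,
                      evaluate_forecast, METRIC_NAMES)
from .models import ModelSpec, enumerate_models
from .selection import AICRecord, aic, ensemble_average, score_family, select_model
from .solver import Schedule, SolverConfig, Trajectory, simulate


@dataclass
class RunConfig:
    scenario: int = 1
    specs: list[str] | None = None        # tokens; default: all 18
    n_samples: int = 100
    seed: int = 0
    threshold: float | None = None        # tumor-extent threshold
    solver: SolverConfig = field(default_factory=SolverConfig)
    calibration: CalibrationOptions = field(default_factory=CalibrationOptions)
    mech: MechanicalParams | None = None

    def resolved_specs(self) -> list[ModelSpec]:
        if self.specs is None:
            return enumerate_models()
        return [ModelSpec.from_token(t) for t in self.specs]


def forecast_samples(dataset: AnimalDataset, result: CalibrationResult,
                     comparison_days: list[float], n_samples: int, seed: int,
                     config: SolverConfig, mech: MechanicalParams | None,
                     ) -> list[Trajectory]:
    """Forward evaluations for parameter sets sampled within the 95% CIs."""
    first_day = result.fitted_visit_days[0]
    first = next(v for v in dataset.visits if v.day == first_day)
    fitted = [v for v in dataset.visits if v.day in result.fitted_visit_days]
    cap = assign_capacity_bounds(fitted)
    schedule = Schedule(rt_days=list(dataset.rt_events),
                        output_days=list(comparison_days))
    out = []
    for params in sample_parameters(result, count=n_samples, seed=seed):
        out.append(simulate(dataset.grid, first.phi_T, first.phi_V, cap, params,
                            result.spec, schedule, mech=mech, config=config,
                            initial_day=first_day))
    return out


@dataclass
class PipelineResult:
    records: list[AICRecord]
    selected: ModelSpec
    selected_report: MetricReport
    ensemble_report: MetricReport
    comparisons: dict[str, float]
    outdir: Path | None


def run_pipeline(dataset: AnimalDataset, config: RunConfig,
                 outdir: str | Path | None = None) -> PipelineResult:
    specs = config.resolved_specs()
    fitted_idx, held_idx = scenario_visits(dataset, config.scenario)
    comparison_idx = held_idx if config.scenario == 2 else fitted_idx[1:]
    if not comparison_idx:
        raise ValueError("no comparison visits for this scenario")
    comparison_days = [dataset.visits[i].day for i in comparison_idx]

    rng = np.random.default_rng(config.seed)
    sub_seeds = rng.integers(0, 2 ** 31 - 1, size=2 * len(specs) + 1)

    results: dict[str, CalibrationResult] = {}
    records: list[AICRecord] = []
    for i, spec in enumerate(specs):
        res = calibrate(dataset, spec, seed=int(sub_seeds[i]),
                        scenario=config.scenario, options=config.calibration)
        results[spec.token] = res
        records.append(AICRecord(spec=spec, k=res.k, n_obs=res.n_obs,
                                 RSS=res.RSS,
                                 AIC=aic(res.k, res.n_obs, max(res.RSS, 1e-300))))
    score_family(records)
    selected = select_model(records)

    threshold = config.threshold
    if threshold is None:
        threshold = 0.5 * (dataset.capacity.theta_min if dataset.capacity else 0.1)

    # per-sample forward evaluations for every model
    all_trajs: dict[str, list[Trajectory]] = {}
    for i, spec in enumerate(specs):
        all_trajs[spec.token] = forecast_samples(
            dataset, results[spec.token], comparison_days, config.n_samples,
            int(sub_seeds[len(specs) + i]), config.solver, config.mech)

    weights = np.array([r.weight for r in records])
    # sample-indexed ensemble: for each sample j, combine all models at j
    ens_trajs: list[Trajectory] = []
    for j in range(config.n_samples):
        phi_T = {}
        phi_V = {}
        for day in comparison_days:
            phi_T[day] = ensemble_average(
                [[all_trajs[s.token][j].phi_T[day]] for s in specs], weights)
            phi_V[day] = ensemble_average(
                [[all_trajs[s.token][j].phi_V[day]] for s in specs], weights)
        ens_trajs.append(Trajectory(days=list(comparison_days), phi_T=phi_T,
                                    phi_V=phi_V, n_fractions=0, final=None))

    selected_report = evaluate_forecast(all_trajs[selected.token], dataset,
                                        comparison_idx, threshold)
    ensemble_report = evaluate_forecast(ens_trajs, dataset, comparison_idx,
                                        threshold)
    comparisons = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for m in METRIC_NAMES:
            a = selected_report.per_set[m].to_numpy()
            b = ensemble_report.per_set[m].to_numpy()
            ok = np.isfinite(a) & np.isfinite(b)
            comparisons[m] = compare_selected_vs_ensemble(a[ok], b[ok]) if ok.any() else float("nan")

    out_path = None
    if outdir is not None:
        out_path = Path(outdir)
        out_path.mkdir(parents=True, exist_ok=True)
        table = pd.DataFrame([{"spec": r.spec.token, "k": r.k, "n": r.n_obs,
                               "RSS": r.RSS, "AIC": r.AIC, "delta": r.delta,
                               "weight": r.weight} for r in records])
        table.to_csv(out_path / "aic.csv", index=False)
        selected_report.per_set.to_csv(out_path / "metrics_selected.csv", index=False)
        ensemble_report.per_set.to_csv(out_path / "metrics_ensemble.csv", index=False)
        manifest = {
            "seed": config.seed,
            "scenario": config.scenario,
            "selected": selected.token,
            "threshold": threshold,
            "n_samples": config.n_samples,
            "comparisons_p": comparisons,
            "calibrations": {t: {"RSS": r.RSS, "k": r.k, "n_obs": r.n_obs,
                                 "params": {n: float(v) for n, v in
                                            zip(r.names, r.x_hat)},
                                 "ci95": r.ci95.tolist()}
                             for t, r in results.items()},
        }
        (out_path / "results.json").write_text(json.dumps(manifest, indent=2))
    return PipelineResult(records=records, selected=selected,
                          selected_report=selected_report,
                          ensemble_report=ensemble_report,
                          comparisons=comparisons, outdir=out_path)
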