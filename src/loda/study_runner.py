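"""Orchestration of the replicated simulation study.

One replicate = simulate a dataset from the scenario's true parameters, fit
each prognostic group's MGLMM by MCMC, compute cross-validated group
probabilities under the requested approaches, pick the ROC-optimal cutoff
per approach, and record the accuracy measures; parameter-recovery tables
aggregate the per-replicate posterior summaries against the generating
truth.  Replicate seeds are spawned deterministically from the master seed,
per-replicate results can be cached to disk and reloaded, and identical
master seeds give byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import metrics_at_cutoff, optimal_cutoff, recovery_summary, roc_curve
from .mcmc_fit import MCMCConfig, fit_group_model, posterior_summary
from .prediction import APPROACHES, PriorProbabilities, loocv_predict, predict_patients
from .synthetic_data import ScenarioDefinition, builtin_scenario, simulate_dataset

__all__ = ["StudyConfig", "StudyResults", "run_study", "format_tables"]

logger = logging.getLogger("loda.study")

_METRIC_COLS = ["cutoff", "sensitivity", "specificity", "pcc", "auc", "ppv", "npv"]
_FLOAT_FMT = "%.10g"


@dataclass
class StudyConfig:
    """Configuration of a replicated simulation study.

    ``groups`` restricts fitting to a subset of groups (recovery-only
    studies); prediction requires all groups and is skipped otherwise.
    ``prediction_draws`` subsamples the retained MCMC draws for the
    probability averaging; ``integration_draws`` is the Monte Carlo size of
    the marginal integral when no closed form applies.
    """

    scenario: str | ScenarioDefinition = "scenario2"
    n_replicates: int = 10
    mcmc_profile: str = "fast"
    loocv_mode: str = "fit_once"
    approaches: tuple[str, ...] = APPROACHES
    integration_draws: int = 300
    prediction_draws: int | None = 100
    seed: int = 0
    out_dir: str | Path | None = None
    groups: tuple[int, ...] | None = None
    run_prediction: bool = True
    positive_group: int = 1

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be at least 1")
        if self.loocv_mode not in ("fit_once", "exact"):
            raise ValueError(f"unknown LOOCV mode {self.loocv_mode!r}")

    def resolve_scenario(self) -> ScenarioDefinition:
        if isinstance(self.scenario, ScenarioDefinition):
            return self.scenario
        return builtin_scenario(self.scenario)


@dataclass
class StudyResults:
    """Aggregated study output: accuracy tables, recovery tables, and the
    retained per-replicate metrics."""

    accuracy: pd.DataFrame
    per_replicate: pd.DataFrame
    recovery: dict[int, pd.DataFrame]
    config: StudyConfig
    n_failed: int = 0


def _replicate_paths(out_dir: Path, r: int, groups):
    metrics = out_dir / f"replicate_{r:03d}_metrics.csv"
    summaries = {g: out_dir / f"replicate_{r:03d}_summary_g{g}.csv" for g in groups}
    return metrics, summaries


def _run_replicate(scn, cfg: StudyConfig, r: int, seeds, groups):
    """One replicate: simulate, fit, predict, score."""
    sim_seed, fit_base, pred_seed = (int(s % (2**31)) for s in seeds)
    patients = simulate_dataset(scn, seed=sim_seed)
    by_group = {g: [p for p in patients if p.group == g] for g in range(scn.n_groups)}
    fits, summaries = {}, {}
    for g in groups:
        mcfg = MCMCConfig.profile(cfg.mcmc_profile, seed=(fit_base + g) % (2**31))
        fits[g] = fit_group_model(by_group[g], scn.specs, mcfg)
        summaries[g] = posterior_summary(fits[g])
    metrics_rows = []
    if cfg.run_prediction and set(groups) == set(range(scn.n_groups)):
        priors = PriorProbabilities.from_counts(
            [len(by_group[g]) for g in range(scn.n_groups)]
        )
        if cfg.loocv_mode == "exact":
            mcfg = MCMCConfig.profile(cfg.mcmc_profile, seed=fit_base)
            table = loocv_predict(
                patients, scn.specs, mcfg, cfg.approaches, mode="exact",
                seed=fit_base, n_draws=cfg.integration_draws,
                prediction_draws=cfg.prediction_draws, priors=priors,
            )
        else:
            table = predict_patients(
                patients,
                scn.specs,
                [fits[g] for g in range(scn.n_groups)],
                priors,
                cfg.approaches,
                n_draws=cfg.integration_draws,
                prediction_draws=cfg.prediction_draws,
                seed=pred_seed,
            )
        labels = (table["true_group"] == cfg.positive_group).astype(int).to_numpy()
        for app in cfg.approaches:
            scores = table[f"P_{app}_{cfg.positive_group}"].to_numpy()
            cut = optimal_cutoff(roc_curve(scores, labels))
            m = metrics_at_cutoff(scores, labels, cut)
            metrics_rows.append({"replicate": r, "approach": app, **m.as_dict()})
    return pd.DataFrame(metrics_rows), summaries


def run_study(cfg: StudyConfig) -> StudyResults:
    """Run (or resume) the replicated study and aggregate its results.

    With ``out_dir`` set, per-replicate metric and posterior-summary tables
    are cached as CSV and reloaded on re-runs, so a partially completed
    study resumes where it stopped.  Failed replicates are logged and
    skipped; more than 20% failures aborts.
    """
    scn = cfg.resolve_scenario()
    groups = tuple(cfg.groups) if cfg.groups is not None else tuple(range(scn.n_groups))
    out_dir = Path(cfg.out_dir) if cfg.out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_replicates)

    metric_frames, summaries_by_rep = [], []
    failures = []
    for r in range(cfg.n_replicates):
        cached = False
        if out_dir is not None:
            mpath, spaths = _replicate_paths(out_dir, r, groups)
            if mpath.exists() and all(p.exists() for p in spaths.values()):
                metric_frames.append(pd.read_csv(mpath))
                summaries_by_rep.append(
                    {g: pd.read_csv(p, index_col="parameter") for g, p in spaths.items()}
                )
                cached = True
        if cached:
            continue
        t0 = time.perf_counter()
        try:
            metrics, summaries = _run_replicate(
                scn, cfg, r, children[r].generate_state(3), groups
            )
        except Exception as exc:  # noqa: BLE001 - replicate-level containment
            logger.warning("replicate %d failed: %s", r, exc)
            failures.append((r, str(exc)))
            if len(failures) > 0.2 * cfg.n_replicates:
                raise RuntimeError(
                    f"{len(failures)} of {cfg.n_replicates} replicates failed; "
                    f"first failure: replicate {failures[0][0]}: {failures[0][1]}"
                ) from exc
            continue
        logger.info("replicate %d done in %.1fs", r, time.perf_counter() - t0)
        metric_frames.append(metrics)
        summaries_by_rep.append(summaries)
        if out_dir is not None:
            mpath, spaths = _replicate_paths(out_dir, r, groups)
            metrics.to_csv(mpath, index=False, float_format=_FLOAT_FMT)
            for g, p in spaths.items():
                summaries[g].to_csv(p, float_format=_FLOAT_FMT)

    per_replicate = (
        pd.concat(metric_frames, ignore_index=True)
        if metric_frames
        else pd.DataFrame(columns=["replicate", "approach", *_METRIC_COLS])
    )
    if len(per_replicate):
        accuracy = (
            per_replicate.groupby("approach", sort=False)[_METRIC_COLS]
            .mean()
            .reindex([a for a in cfg.approaches if a in set(per_replicate["approach"])])
        )
    else:
        accuracy = pd.DataFrame(columns=_METRIC_COLS)
    recovery = {}
    for g in groups:
        reps = [s[g] for s in summaries_by_rep]
        if reps:
            recovery[g] = recovery_summary(reps, scn.group_params[g], scn.specs)
    return StudyResults(
        accuracy=accuracy,
        per_replicate=per_replicate,
        recovery=recovery,
        config=cfg,
        n_failed=len(failures),
    )


def _config_digest(cfg: StudyConfig) -> str:
    payload = {
        k: (v if isinstance(v, (int, float, str, type(None), list, tuple)) else str(v))
        for k, v in dataclasses.asdict(cfg).items()
        if k != "out_dir"
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def format_tables(results: StudyResults, out_dir: str | Path) -> dict[str, Path]:
    """Write the study's aggregate tables as CSV plus a provenance manifest.

    Emits the mean accuracy table (approaches as rows), the per-replicate
    metric table, one recovery table per fitted group, a parameter echo of
    the scenario's true values, and ``manifest.json`` recording the seed and
    a configuration digest.  Output bytes depend only on the results.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    path = out_dir / "accuracy.csv"
    results.accuracy.to_csv(path, float_format=_FLOAT_FMT, index_label="approach")
    written["accuracy"] = path

    path = out_dir / "per_replicate_metrics.csv"
    results.per_replicate.to_csv(path, index=False, float_format=_FLOAT_FMT)
    written["per_replicate"] = path

    scn = results.config.resolve_scenario()
    from .model_core import parameter_vector  # local import to avoid cycle at module load

    truth_rows = []
    for g, params in enumerate(scn.group_params):
        for name, value in parameter_vector(params, scn.specs).items():
            truth_rows.append({"group": g, "parameter": name, "value": value})
    path = out_dir / "true_parameters.csv"
    pd.DataFrame(truth_rows).to_csv(path, index=False, float_format=_FLOAT_FMT)
    written["true_parameters"] = path

    for g, table in results.recovery.items():
        path = out_dir / f"recovery_group{g}.csv"
        table.to_csv(path, float_format=_FLOAT_FMT)
        written[f"recovery_group{g}"] = path

    manifest = {
        "seed": results.config.seed,
        "scenario": scn.name,
        "n_replicates": results.config.n_replicates,
        "n_failed": results.n_failed,
        "mcmc_profile": results.config.mcmc_profile,
        "approaches": list(results.config.approaches),
        "config_digest": _config_digest(results.config),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written["manifest"] = path
    return written
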