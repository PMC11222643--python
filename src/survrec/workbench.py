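"""Experiment orchestration: one config in, a reproducible result bundle out.

``run_experiment`` ties the stages together the way the study design
prescribes: simulate (or load) a cohort, carve off the external-year
cohort, split the remainder 70/30, fit the requested model variants on
the training set, convert predicted per-arm curves to ITEs and
recommendations, evaluate recommendation consistency (raw and IPTW) on
the test and external-test sets, and run the interpretation layers.
Every artifact lands in the output directory with the seeds that
produced it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .causal import evaluate_recommender
from .cohort import COHORT_COLUMNS, CohortConfig, generate_cohort
from .interpret import ite_insight_regression, mediation_inde_inie
from .ite import (DEFAULT_TAU, build_ite_table, derive_stages, ite_rst,
                  nccn_recommend)
from .models import (NetConfig, fit_balanced_net, fit_t_cph, fit_t_deepsurv,
                     predict_survival, save_model)
from .preprocess import encode_covariates, split_cohort

__all__ = ["ExperimentConfig", "run_experiment", "read_cohort_csv",
           "write_cohort_csv"]

log = logging.getLogger("survrec")

_EXPECTED_DTYPES = {
    "patient_id": int, "age": float, "tumor_size_mm": float,
    "positive_nodes": int, "grade": int, "region": int,
    "diagnosis_year": int, "treatment": int, "time_months": float,
    "event": int,
}


def read_cohort_csv(path) -> pd.DataFrame:
    """Strict reader for the cohort schema; any missing value or unknown
    column is a hard error (incomplete records are excluded upstream,
    never imputed)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    extra = [c for c in df.columns if c not in COHORT_COLUMNS]
    if extra:
        raise ValueError(f"unrecognized column(s): {extra}")
    missing_cols = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"missing column(s): {missing_cols}")
    for col in COHORT_COLUMNS:
        empty = df.index[df[col].str.strip() == ""]
        if len(empty):
            raise ValueError(
                f"missing value in column {col!r} at data row(s) "
                f"{[int(i) + 2 for i in empty[:5]]} (1-based file lines)")
    out = df.copy()
    for col, typ in _EXPECTED_DTYPES.items():
        try:
            out[col] = df[col].astype(float).astype(typ) if typ is int \
                else df[col].astype(typ)
        except ValueError as exc:
            raise ValueError(f"malformed value in column {col!r}: {exc}") from exc
    if (out["time_months"] <= 0).any():
        raise ValueError("time_months must be strictly positive")
    for col in ("treatment", "event"):
        if not set(out[col].unique()) <= {0, 1}:
            raise ValueError(f"{col} must be 0/1")
    return out[COHORT_COLUMNS]


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort[COHORT_COLUMNS].to_csv(path, index=False)


@dataclass
class ExperimentConfig:
    """Everything one run needs; serializable to/from JSON."""

    cohort: CohortConfig | None = None       # simulate ...
    cohort_csv: str | None = None            # ... or load
    models: tuple = ("t_cph",)               # subset of t_cph/t_deepsurv/bites/snb
    net_config: NetConfig = field(default_factory=NetConfig)
    external_year: int = 2010
    tau: float = DEFAULT_TAU
    n_boot: int = 200
    seed: int = 0
    out_dir: str = "survrec_run"

    def to_json(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            raise TypeError(type(o).__name__)
        return json.dumps(dataclasses.asdict(self), default=enc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ExperimentConfig":
        d = json.loads(text)
        if d.get("cohort"):
            d["cohort"] = CohortConfig(**d["cohort"])
        if d.get("net_config"):
            d["net_config"] = NetConfig(**{k: tuple(v) if isinstance(v, list)
                                           else v
                                           for k, v in d["net_config"].items()})
        if isinstance(d.get("models"), list):
            d["models"] = tuple(d["models"])
        return cls(**d)


def _fit_model(kind: str, X, treatment, times, events, cfg: NetConfig,
               feature_names):
    labels = (times, events)
    if kind == "t_cph":
        m0, m1 = treatment == 0, treatment == 1
        return fit_t_cph(X[m0], (times[m0], events[m0]),
                         X[m1], (times[m1], events[m1]),
                         feature_names=feature_names)
    if kind == "t_deepsurv":
        m0, m1 = treatment == 0, treatment == 1
        return fit_t_deepsurv(X[m0], (times[m0], events[m0]),
                              X[m1], (times[m1], events[m1]),
                              cfg, feature_names=feature_names)
    if kind in ("bites", "snb"):
        return fit_balanced_net(X, treatment, labels, cfg, variant=kind,
                                feature_names=feature_names)
    raise ValueError(f"unknown model kind {kind!r}")


def run_experiment(config: ExperimentConfig) -> dict:
    """Execute the full pipeline and write the result bundle.

    Returns a dict of the in-memory artifacts (cohort, split, per-model
    ITE tables and effect reports, interpretation reports).  Errors in a
    stage propagate with the stage name prefixed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    stage = "setup"
    run_log = {"seed": config.seed, "version": __version__, "stages": {}}

    def tick(name):
        nonlocal stage
        run_log["stages"][stage] = round(time.time() - t_start, 2)
        stage = name
        log.info("stage: %s", name)

    try:
        tick("cohort")
        if config.cohort_csv:
            cohort = read_cohort_csv(config.cohort_csv)
            truth = None
        else:
            ccfg = config.cohort or CohortConfig(seed=config.seed)
            cohort, truth = generate_cohort(ccfg)
            write_cohort_csv(cohort, out / "cohort.csv")
            truth.frame.to_csv(out / "cohort_truth.csv", index=False)

        tick("split")
        plan = split_cohort(cohort, config.external_year, seed=config.seed)
        (out / "split_plan.json").write_text(plan.to_json(cohort))

        tick("encode")
        # full dummies for the neural models, reference-dropped for the
        # linear T-learner (full encoding is singular in a linear fit)
        dms = {"onehot_full": encode_covariates(cohort, fit_on=plan.train,
                                                scheme="onehot_full"),
               "onehot_drop": encode_covariates(cohort, fit_on=plan.train,
                                                scheme="onehot_drop")}
        times = cohort["time_months"].to_numpy(float)
        events = cohort["event"].to_numpy(int)
        treatment = cohort["treatment"].to_numpy(int)
        grid = np.arange(0.0, config.tau + 1.0)

        results = {"cohort": cohort, "truth": truth, "split": plan,
                   "models": {}}
        report_rows = {}
        for kind in config.models:
            tick(f"fit:{kind}")
            dm = dms["onehot_drop" if kind == "t_cph" else "onehot_full"]
            X = dm.matrix
            tr = plan.train
            model = _fit_model(kind, X[tr], treatment[tr], times[tr],
                               events[tr], config.net_config, dm.feature_names)
            save_model(model, str(out / f"model_{kind}.json"))

            tick(f"recommend:{kind}")
            curves = predict_survival(model, X, grid,
                                      cohort["patient_id"].to_numpy())
            ite = ite_rst(curves, tau=config.tau)
            table = build_ite_table(cohort["patient_id"], ite, treatment,
                                    tau=config.tau)
            table.to_csv(out / f"ite_{kind}.csv", index=False)

            tick(f"evaluate:{kind}")
            reports = {}
            for split_name, idx in (("test", plan.test),
                                    ("external", plan.external)):
                if len(idx) == 0:
                    continue
                rep = evaluate_recommender(
                    cohort.iloc[idx], table["recommended"].to_numpy()[idx],
                    tau=config.tau, n_boot=config.n_boot, seed=config.seed,
                    model=model, design=X[idx], grid=grid)
                reports[split_name] = rep
                report_rows[f"{kind}/{split_name}"] = rep.to_dict()
            results["models"][kind] = {"model": model, "ite_table": table,
                                       "reports": reports}

        # guideline comparator on the same splits
        tick("evaluate:nccn")
        t_stage, n_stage = derive_stages(cohort["tumor_size_mm"],
                                         cohort["positive_nodes"])
        nccn = nccn_recommend(t_stage, cohort["tumor_size_mm"], n_stage)
        for split_name, idx in (("test", plan.test),
                                ("external", plan.external)):
            if len(idx) == 0:
                continue
            rep = evaluate_recommender(cohort.iloc[idx], nccn[idx],
                                       tau=config.tau, n_boot=config.n_boot,
                                       seed=config.seed)
            report_rows[f"nccn/{split_name}"] = rep.to_dict()
        (out / "effect_reports.json").write_text(
            json.dumps(report_rows, indent=2))

        # interpretation on the combined test + external population,
        # using the first requested model's ITEs
        tick("interpret")
        first = config.models[0]
        table = results["models"][first]["ite_table"]
        comb = np.concatenate([plan.test, plan.external]).astype(int)
        cov_natural = pd.DataFrame({
            "age": cohort["age"].to_numpy(float)[comb],
            "tumor_size_mm": cohort["tumor_size_mm"].to_numpy(float)[comb],
            "positive_nodes": cohort["positive_nodes"].to_numpy(float)[comb],
            "upper_inner": (cohort["location"].to_numpy()[comb]
                            == "upper_inner").astype(float),
        })
        insight = ite_insight_regression(
            table["ite_rst"].to_numpy()[comb], cov_natural,
            cohort["region"].to_numpy()[comb])
        (out / "insight_report.json").write_text(
            json.dumps(insight.to_dict(), indent=2))
        (out / "insight_report.txt").write_text(insight.to_text())

        consis = table["consistent"].to_numpy()[comb].astype(int)
        dm_drop = encode_covariates(cohort.iloc[comb], scheme="onehot_drop")
        died_by_tau = ((times[comb] <= config.tau)
                       & (events[comb] == 1)).astype(float)
        mediation = mediation_inde_inie(
            consis, treatment[comb][:, None], dm_drop.matrix, died_by_tau,
            n_boot=config.n_boot, seed=config.seed)
        (out / "mediation_report.json").write_text(
            json.dumps(mediation.to_dict(), indent=2))
        results["insight"] = insight
        results["mediation"] = mediation

        tick("done")
        run_log["total_seconds"] = round(time.time() - t_start, 2)
        (out / "run_log.json").write_text(json.dumps(run_log, indent=2))
        (out / "experiment_config.json").write_text(config.to_json())
        return results
    except Exception as exc:
        raise RuntimeError(f"experiment failed in stage {stage!r}: {exc}") from exc
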