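"""End-to-end experiment: calibrate, redesign DCGs, rake, evaluate.

The orchestrated stages mirror how a risk-equalization model is
maintained in practice:

1. simulate (or load) a calibration population with known truth;
2. fit the partial model and build the traditional two-layer DCG scheme
   from per-dxgroup mean residual spending (weighted Ward clustering);
3. calibrate four model variants on the population:
   ``M0`` (all classifications, no DCG adjuster), ``M1`` (plus the
   traditional pDCG/sDCG dummies), ``Mfull`` (plus one dummy per
   dxgroup) and ``M2`` (plus the interval-clustered multi-qualification
   DCG counts derived from ``Mfull``'s coefficients);
4. draw the morbidity-enriched subsample, rake its weights to the
   population's risk-class margins and apply the spending correction;
5. evaluate: fit measures per model, per-dxgroup and per-condition mean
   financial results, WMAFR and bracket summaries, multimorbidity
   strata, and model-comparison tests.

Everything is deterministic under the configured seed; with an output
directory every intermediate artifact is serialized and re-loadable by
the module that produced it.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import dcg, evaluation, rebalance, synthetic
from .calibration import CalibratedModel, fit_partial, fit_wls
from .population import (
    build_design,
    drop_empty_columns,
    dxgroup_indicator_matrix,
    write_population,
    write_scheme,
)

__all__ = ["ExperimentConfig", "EvaluationReport", "run_experiment"]

logger = logging.getLogger("riskeq.pipeline")

MODEL_NAMES = ("M0", "M1", "M2", "Mfull")


@dataclass(frozen=True)
class ExperimentConfig:
    """All settings of one experiment run."""

    generator: synthetic.GeneratorConfig = field(
        default_factory=synthetic.GeneratorConfig
    )
    n_primary: int = 15
    n_secondary: int = 7
    max_range: float = 500.0
    raking_tolerance: float = 1e-8
    raking_max_iterations: int = 1000
    top_bin: int = 8
    bracket_bound: float = 500.0

    @staticmethod
    def from_json(path) -> "ExperimentConfig":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        gen = payload.pop("generator", {})
        blocks = gen.pop("morbidity_blocks", None)
        if blocks is not None:
            gen["morbidity_blocks"] = tuple(
                synthetic.MorbidityBlock(
                    name=b["name"],
                    prevalence=b["prevalence"],
                    labels=tuple(b["labels"]),
                    class_shares=tuple(b["class_shares"]),
                    coefficients=tuple(b["coefficients"]),
                    frailty_power=b.get("frailty_power", 0.5),
                )
                for b in blocks
            )
        for key in ("age_gender_shares", "age_gender_coefficients",
                    "severe_coef_range", "persistence_range",
                    "candidate_prevalence_range"):
            if key in gen:
                gen[key] = tuple(gen[key])
        return ExperimentConfig(
            generator=synthetic.GeneratorConfig(**gen), **payload
        )


@dataclass
class EvaluationReport:
    """Aggregated experiment outcome (JSON-serializable via to_dict)."""

    metadata: dict
    fit: dict                 # model -> {"r2": ..., "cpm": ...}
    dxgroup_results: dict     # model -> {dxgroup -> GroupResult}
    wmafr_dxgroup: dict       # model -> euros/yr
    brackets: dict            # model -> bracket summaries
    dxcount_strata: dict      # model -> {stratum -> GroupResult}
    stratum_frequencies: dict  # stratum -> weighted share
    condition_results: dict   # model -> {condition -> GroupResult}
    wmafr_condition: dict     # model -> euros/yr
    chronic_results: dict     # model -> {"chronic"/"not_chronic" -> GroupResult}
    condition_strata: dict    # model -> {stratum -> GroupResult}
    significant_negative: dict  # model -> count at p < 0.01
    model_comparison: dict    # condition -> GroupResult of M2 - M0 difference
    raking: dict

    def to_dict(self) -> dict:
        def conv(obj):
            if isinstance(obj, evaluation.GroupResult):
                return asdict(obj)
            if isinstance(obj, dict):
                return {k: conv(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [conv(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj
        return conv(
            {
                "metadata": self.metadata,
                "fit": self.fit,
                "dxgroup_results": self.dxgroup_results,
                "wmafr_dxgroup": self.wmafr_dxgroup,
                "brackets": self.brackets,
                "dxcount_strata": self.dxcount_strata,
                "stratum_frequencies": self.stratum_frequencies,
                "condition_results": self.condition_results,
                "wmafr_condition": self.wmafr_condition,
                "chronic_results": self.chronic_results,
                "condition_strata": self.condition_strata,
                "significant_negative": self.significant_negative,
                "model_comparison": self.model_comparison,
                "raking": self.raking,
            }
        )

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def _stage(name: str, started: float, **detail) -> None:
    logger.info(json.dumps(
        {"stage": name, "seconds": round(time.perf_counter() - started, 3),
         **detail},
        sort_keys=True,
    ))


def _occupied_columns(labels, mat):
    kept, filtered = drop_empty_columns(labels, mat)
    if len(kept) < len(labels):
        dropped = sorted(set(labels) - set(kept))
        logger.info(json.dumps({"stage": "design",
                                "dropped_empty_dcg_columns": dropped}))
    return kept, filtered


def _dcg_scheme_payload(scheme: dcg.DCGScheme) -> dict:
    return {
        "method": scheme.method,
        "labels": list(scheme.labels),
        "mapping": scheme.mapping,
        "secondary_mapping": scheme.secondary_mapping,
        "ranking": list(scheme.ranking),
        "cluster_stats": scheme.cluster_stats,
        "max_range": scheme.max_range,
    }


def run_experiment(config: ExperimentConfig,
                   out_dir: str | Path | None = None) -> EvaluationReport:
    """Run every stage and return (and optionally serialize) the report."""
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    t0 = time.perf_counter()
    gen = config.generator
    scheme = gen.scheme()
    records, truth = synthetic.generate_population(gen)
    _stage("simulate", t0, n=len(records))

    catalogue = scheme.dxgroup_catalogue
    if out is not None:
        write_population(records, out / "population.csv", scheme)
        write_scheme(scheme, out / "scheme.json")
        with open(out / "truth.json", "w", encoding="utf-8") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)

    # --- traditional scheme from the partial model -----------------------
    t = time.perf_counter()
    partial = fit_partial(records, scheme)
    stats = dcg.dxgroup_stats(records, catalogue, residuals=partial.residuals)
    traditional = dcg.build_traditional_scheme(
        stats, config.n_primary, config.n_secondary
    )
    _stage("traditional_scheme", t,
           n_primary=config.n_primary, n_secondary=config.n_secondary)

    # --- calibrate model variants ----------------------------------------
    t = time.perf_counter()
    designs = {
        "M0": build_design(records, scheme, validate=False),
        "M1": build_design(records, scheme,
                           extra=_occupied_columns(
                               *dcg.traditional_columns(records, traditional)),
                           validate=False),
        "Mfull": build_design(records, scheme,
                              extra=dxgroup_indicator_matrix(records, catalogue),
                              validate=False),
    }
    models: dict[str, CalibratedModel] = {
        name: fit_wls(d) for name, d in designs.items()
    }
    interval = dcg.build_multi_scheme(models["Mfull"], config.max_range)
    designs["M2"] = build_design(
        records, scheme, extra=dcg.multi_columns(records, interval),
        validate=False,
    )
    models["M2"] = fit_wls(designs["M2"])
    _stage("calibrate", t, n_dcg_interval=len(interval.labels))
    if out is not None:
        for name, model in models.items():
            model.to_json(out / f"model_{name}.json")
        for tag, sch in (("traditional", traditional), ("interval", interval)):
            with open(out / f"scheme_{tag}.json", "w", encoding="utf-8") as fh:
                json.dump(_dcg_scheme_payload(sch), fh, indent=2)

    # --- population-level evaluation --------------------------------------
    t = time.perf_counter()
    y = designs["M0"].y
    w = designs["M0"].w
    fit = {
        name: {
            "r2": evaluation.r_squared(y, m.fitted, w),
            "cpm": evaluation.cpm(y, m.fitted, w),
        }
        for name, m in models.items()
    }

    member_idx: dict[str, list[int]] = {g: [] for g in catalogue}
    for i, rec in enumerate(records):
        for g in rec.dxgroups:
            member_idx[g].append(i)
    occupied = {g: np.asarray(ix) for g, ix in member_idx.items() if ix}

    dxgroup_results: dict[str, dict[str, evaluation.GroupResult]] = {}
    wmafr_dxgroup: dict[str, float] = {}
    brackets: dict[str, dict] = {}
    for name in ("M1", "M2", "Mfull"):
        res = {
            g: evaluation.mfr(ix, y, models[name].fitted, w, group_id=g)
            for g, ix in occupied.items()
        }
        dxgroup_results[name] = res
        values = list(res.values())
        wmafr_dxgroup[name] = evaluation.wmafr(values)
        brackets[name] = {
            "within_bound": evaluation.bracket_share(values,
                                                     config.bracket_bound),
            **evaluation.undercompensation_brackets(values),
        }

    strata = evaluation.multimorbidity_partition(records, "dxgroups",
                                                 config.top_bin)
    stratum_frequencies = {
        s: float(w[ix].sum() / w.sum()) for s, ix in strata.items()
    }
    dxcount_strata = {
        name: {
            s: evaluation.mfr(ix, y, models[name].fitted, w, group_id=s)
            for s, ix in strata.items()
        }
        for name in ("M1", "M2")
    }
    _stage("evaluate_population", t)

    # --- subsample: rake, correct, condition-level evaluation --------------
    t = time.perf_counter()
    sample = synthetic.generate_subsample(records, gen)
    dims = tuple(c.name for c in scheme.classifications)
    targets = rebalance.population_margins(records, dims)
    raked = rebalance.ipf_rake(
        sample, targets,
        rebalance.RakingSpec(dims, config.raking_tolerance,
                             config.raking_max_iterations),
    )
    sample_y = np.array([r.spending_annualized for r in sample])
    pop_mean = float((w * y).sum() / w.sum())
    corrected_y, factor = rebalance.spending_correction(
        sample_y, raked.weights, pop_mean
    )
    raking_report = {
        "sample_size": len(sample),
        "iterations": raked.iterations,
        "max_discrepancy": raked.max_discrepancy,
        "converged": raked.converged,
        "correction_factor": factor,
        "population_mean": pop_mean,
        "significance_test": "weighted z-test, Kish effective n "
                             "(normal approximation)",
    }
    if out is not None:
        with open(out / "raking.json", "w", encoding="utf-8") as fh:
            json.dump(raking_report, fh, indent=2)

    sample_designs = {
        "M0": build_design(sample, scheme, validate=False),
        "M2": build_design(sample, scheme,
                           extra=dcg.multi_columns(sample, interval),
                           validate=False),
    }
    sample_pred = {
        name: sample_designs[name].matrix @ models[name].coefficients
        for name in ("M0", "M2")
    }
    sw = raked.weights

    cond_idx: dict[str, list[int]] = {}
    for i, rec in enumerate(sample):
        for c in rec.conditions:
            cond_idx.setdefault(c, []).append(i)
    cond_groups = {c: np.asarray(ix) for c, ix in sorted(cond_idx.items())}

    condition_results: dict[str, dict[str, evaluation.GroupResult]] = {}
    wmafr_condition: dict[str, float] = {}
    chronic_results: dict[str, dict[str, evaluation.GroupResult]] = {}
    condition_strata: dict[str, dict[str, evaluation.GroupResult]] = {}
    significant_negative: dict[str, int] = {}
    chronic_mask = np.array([len(r.conditions) > 0 for r in sample])
    cstrata = evaluation.multimorbidity_partition(sample, "conditions",
                                                  config.top_bin)
    for name in ("M0", "M2"):
        res = {
            c: evaluation.mfr(ix, corrected_y, sample_pred[name], sw,
                              group_id=c)
            for c, ix in cond_groups.items()
        }
        condition_results[name] = res
        wmafr_condition[name] = evaluation.wmafr(list(res.values()))
        chronic_results[name] = {
            "chronic": evaluation.mfr(chronic_mask, corrected_y,
                                      sample_pred[name], sw, "chronic"),
            "not_chronic": evaluation.mfr(~chronic_mask, corrected_y,
                                          sample_pred[name], sw,
                                          "not_chronic"),
        }
        condition_strata[name] = {
            s: evaluation.mfr(ix, corrected_y, sample_pred[name], sw, s)
            for s, ix in cstrata.items()
        }
        significant_negative[name] = evaluation.count_significant_negative(
            list(res.values()), alpha=0.01
        )
    model_comparison = evaluation.compare_models(
        sample_pred["M2"], sample_pred["M0"], cond_groups, sw
    )
    _stage("evaluate_subsample", t, sample=len(sample))

    report = EvaluationReport(
        metadata={
            "seed": gen.seed,
            "n_persons": gen.n_persons,
            "n_dxgroups": gen.n_dxgroups,
            "n_primary": config.n_primary,
            "n_secondary": config.n_secondary,
            "max_range": config.max_range,
            "n_interval_dcgs": len(interval.labels),
            "models": list(models),
        },
        fit=fit,
        dxgroup_results=dxgroup_results,
        wmafr_dxgroup=wmafr_dxgroup,
        brackets=brackets,
        dxcount_strata=dxcount_strata,
        stratum_frequencies=stratum_frequencies,
        condition_results=condition_results,
        wmafr_condition=wmafr_condition,
        chronic_results=chronic_results,
        condition_strata=condition_strata,
        significant_negative=significant_negative,
        model_comparison=model_comparison,
        raking=raking_report,
    )
    if out is not None:
        report.save(out / "report.json")
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(
                {"seed": gen.seed, "outputs": sorted(
                    p.name for p in out.iterdir())},
                fh, indent=2,
            )
    _stage("done", t0)
    return report
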