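"""End-to-end study orchestration: generate → accumulate → extract → select →
evaluate → transfer, as a single reproducible run.

A :class:`RunConfig` bundles the two cohort specs, EQD2 and discretization
settings, the selection and evaluation configs and one global seed that fans
out deterministically to every stage.  :func:`run_full_study` produces, in a
run directory: feature tables (CSV), selection results (CSV/JSON),
per-split metric CSVs and summary JSON for the four esophageal-cohort models
and the five lung-cohort transfer models, a pairwise Z-test table and a
``MANIFEST.json`` capturing the configuration and library versions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortSpec, generate_cohort
from .evaluation import EvalConfig, PneumonitisModel, PneumonitisResults, compare_models
from .extract import extract_cohort_features, feature_group_columns
from .selection import SelectionConfig, SelectionResult, select_features
from .volume_ops import ANALYSIS_SPACING_MM

__all__ = ["RunConfig", "run_full_study", "StageError"]

logger = logging.getLogger(__name__)

MODEL_GROUPS = ("dvh", "dosiomic", "radiomic", "combined")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _stage_seed(global_seed: int, stage_index: int) -> int:
    """Counter-based seed fan-out: independent, reproducible per stage."""
    ss = np.random.SeedSequence((int(global_seed) % (2**31), int(stage_index)))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    alpha_beta: float = 3.0
    use_eqd2: bool = True
    target_spacing_mm: tuple[float, float, float] = ANALYSIS_SPACING_MM
    esophageal: CohortSpec = field(
        default_factory=lambda: CohortSpec(n_patients=101, cancer_type="esophageal",
                                           target_prevalence=0.62)
    )
    lung: CohortSpec = field(
        default_factory=lambda: CohortSpec(n_patients=93, cancer_type="lung",
                                           target_prevalence=0.17)
    )
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    evaluation: EvalConfig = field(default_factory=EvalConfig)

    def resolved(self) -> "RunConfig":
        """Fan the global seed out to every stage-level config."""
        return dataclasses.replace(
            self,
            esophageal=dataclasses.replace(self.esophageal, seed=_stage_seed(self.seed, 1)),
            lung=dataclasses.replace(self.lung, seed=_stage_seed(self.seed, 2)),
            selection=dataclasses.replace(self.selection, seed=_stage_seed(self.seed, 3)),
            evaluation=dataclasses.replace(self.evaluation, seed=_stage_seed(self.seed, 4)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        for key in ("seed", "alpha_beta", "use_eqd2"):
            if key in raw:
                kwargs[key] = raw[key]
        if "target_spacing_mm" in raw:
            kwargs["target_spacing_mm"] = tuple(raw["target_spacing_mm"])
        for key, klass, preset in (
            ("esophageal", CohortSpec, {"cancer_type": "esophageal",
                                        "n_patients": 101, "target_prevalence": 0.62}),
            ("lung", CohortSpec, {"cancer_type": "lung",
                                  "n_patients": 93, "target_prevalence": 0.17}),
            ("selection", SelectionConfig, {}),
            ("evaluation", EvalConfig, {}),
        ):
            if key in raw:
                params = dict(preset)
                params.update(raw[key] or {})
                if "reg_strength_grid" in params:
                    params["reg_strength_grid"] = tuple(params["reg_strength_grid"])
                if klass is CohortSpec:
                    for tup in ("grid_shape", "voxel_spacing_mm", "n_fractions_range"):
                        if tup in params:
                            params[tup] = tuple(params[tup])
                kwargs[key] = klass(**params)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        def conv(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return {
            "seed": self.seed,
            "alpha_beta": self.alpha_beta,
            "use_eqd2": self.use_eqd2,
            "target_spacing_mm": list(self.target_spacing_mm),
            "esophageal": conv(self.esophageal),
            "lung": conv(self.lung),
            "selection": conv(self.selection),
            "evaluation": conv(self.evaluation),
        }


def _write_results(results: PneumonitisResults, path: Path) -> None:
    pd.DataFrame({
        "split": np.arange(results.roc_aucs.size),
        "rocauc": results.roc_aucs,
        "prauc": results.pr_aucs,
        "reg_strength": results.chosen_strengths,
    }).to_csv(path, index=False, float_format="%.10g")


def _summary_dict(results: PneumonitisResults) -> dict:
    s = results.summary()
    return {
        metric: {k: float(s.loc[metric, k]) for k in ("mean", "sd", "p10", "p90")}
        for metric in ("rocauc", "prauc")
    }


def run_full_study(config: RunConfig, out_dir: str | Path) -> Path:
    """Run the full analysis; returns the run directory.

    Any stage failure is re-raised as :class:`StageError` naming the stage.
    """
    config = config.resolved()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name, fn):
        logger.info("stage %s ...", name)
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise StageError(name, str(exc)) from exc

    cohort_a = stage("generate-esophageal", lambda: generate_cohort(config.esophageal))
    cohort_b = stage("generate-lung", lambda: generate_cohort(config.lung))

    extract = lambda pats: extract_cohort_features(  # noqa: E731
        pats, alpha_beta=config.alpha_beta, use_eqd2=config.use_eqd2,
        target_spacing_mm=config.target_spacing_mm,
    )
    table_a = stage("extract-esophageal", lambda: extract(cohort_a))
    table_b = stage("extract-lung", lambda: extract(cohort_b))
    table_a.to_csv(out / "features_esophageal.csv", index=False, float_format="%.10g")
    table_b.to_csv(out / "features_lung.csv", index=False, float_format="%.10g")
    y_a = table_a["label"].to_numpy()
    y_b = table_b["label"].to_numpy()

    selections: dict[str, SelectionResult] = {}
    for group in ("dvh", "dosiomic", "radiomic"):
        selections[group] = stage(
            f"select-{group}",
            lambda g=group: select_features(table_a, y_a, g, config.selection),
        )
        selections[group].to_frame().to_csv(out / f"selection_{group}.csv", index=False)
    with open(out / "selection.json", "w") as fh:
        json.dump({g: list(r.selected) for g, r in selections.items()}, fh, indent=2)

    feature_sets = {
        "dvh": list(selections["dvh"].selected),
        "dosiomic": list(selections["dosiomic"].selected),
        "radiomic": list(selections["radiomic"].selected),
        "combined": list(selections["dosiomic"].selected)
        + list(selections["radiomic"].selected),
    }

    summaries: dict[str, dict] = {"esophageal": {}, "lung": {}}
    results_a: dict[str, PneumonitisResults] = {}
    for model in MODEL_GROUPS:
        res = stage(
            f"evaluate-esophageal-{model}",
            lambda m=model: PneumonitisModel(
                table_a, y_a, feature_sets[m], config.evaluation,
                name=f"esophageal-{m}",
            ).fit(),
        )
        results_a[model] = res
        _write_results(res, out / f"metrics_esophageal_{model}.csv")
        summaries["esophageal"][model] = _summary_dict(res)

    # transfer: esophageal-selected features applied to the lung cohort,
    # plus the DVH_lung baseline selected on the lung cohort itself
    results_b: dict[str, PneumonitisResults] = {}
    dvh_lung_sel = stage(
        "select-dvh-lung",
        lambda: select_features(table_b, y_b, "dvh", config.selection),
    )
    dvh_lung_sel.to_frame().to_csv(out / "selection_dvh_lung.csv", index=False)
    transfer_sets = dict(feature_sets)
    transfer_sets["dvh_lung"] = list(dvh_lung_sel.selected)
    for model in ("dvh_lung",) + MODEL_GROUPS:
        res = stage(
            f"evaluate-lung-{model}",
            lambda m=model: PneumonitisModel(
                table_b, y_b, transfer_sets[m], config.evaluation,
                name=f"lung-{m}",
            ).fit(),
        )
        results_b[model] = res
        _write_results(res, out / f"metrics_lung_{model}.csv")
        summaries["lung"][model] = _summary_dict(res)

    rows = []
    for cohort, results in (("esophageal", results_a), ("lung", results_b)):
        names = list(results)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                for metric in ("rocauc", "prauc"):
                    z, p = compare_models(results[a], results[b], metric=metric)
                    rows.append({"cohort": cohort, "model_a": a, "model_b": b,
                                 "metric": metric, "z": z, "p": p})
    pd.DataFrame(rows).to_csv(out / "comparisons.csv", index=False, float_format="%.10g")

    with open(out / "summary.json", "w") as fh:
        json.dump(summaries, fh, indent=2)

    cfg_dict = config.to_dict()
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True).encode()
    ).hexdigest()
    import scipy
    import sklearn
    import statsmodels

    manifest = {
        "config": cfg_dict,
        "config_sha256": cfg_hash,
        "n_patients": {"esophageal": len(cohort_a), "lung": len(cohort_b)},
        "versions": {
            "dosiomics_rp": __import__("dosiomics_rp").__version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
            "statsmodels": statsmodels.__version__,
        },
    }
    with open(out / "MANIFEST.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    logger.info("run complete: %s", out)
    return out
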