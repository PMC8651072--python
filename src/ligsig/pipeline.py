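"""End-to-end workflow: curate -> featurize -> split -> train -> evaluate.

A single YAML-able config dict drives the whole run; every artifact is
written as delimited text or JSON next to a manifest recording the
config hash, seeds and all decisions (chosen algorithm, selected
features, metrics), so identical config + seed reproduces identical
artifacts.  All randomness flows from one top-level seed, expanded per
stage with fixed offsets.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd

from .curation import (
    CuratedLigand,
    read_ligand_table,
    curate_dataset,
    write_curated_table,
)
from .descriptors import combined_feature_matrix
from .modeling import (
    ALGORITHMS,
    MetricsReport,
    cross_validate,
    evaluate,
    greedy_forward_selection,
    outlier_trimmed_metrics,
    select_best_model,
    train_model,
)
from .signatures import CutoffSchedule
from .splitting import make_split_plan

#: Documented defaults; CLI flags and config files override these.
DEFAULT_CONFIG: dict = {
    "delimiter": ",",
    "max_spread": 1.0,
    "aggregate_statistic": "mean",
    "schedule": {"min": 1, "max": 10, "step": 1},
    "blind_fraction": 0.1,
    "similarity_threshold": 0.8,
    "fingerprint_bits": 2048,
    "cv_folds": 10,
    "stratify_bins": 10,
    "algorithms": list(ALGORITHMS),
    "n_estimators": None,  # None = library default ensemble size
    "trim_fraction": 0.1,
    "seed": 0,
}


class ConfigError(KeyError):
    """Raised when a config key is unknown."""


def resolve_config(config: dict | None) -> dict:
    """Overlay a user config on the documented defaults.

    Unknown keys raise, naming the key, so typos never silently fall
    back to a default.
    """
    merged = dict(DEFAULT_CONFIG)
    for key, val in (config or {}).items():
        if key not in merged and key not in ("input", "output_dir"):
            known = ", ".join(sorted(merged))
            raise ConfigError(f"unknown config key {key!r}; known keys: {known}")
        merged[key] = val
    return merged


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def schedule_from_config(config: dict) -> CutoffSchedule:
    s = config["schedule"]
    return CutoffSchedule(min=s["min"], max=s["max"], step=s["step"])


def featurize(smiles_list: Sequence[str], config: dict | None = None) -> pd.DataFrame:
    """Combined [signatures || descriptors] feature table under a config."""
    config = resolve_config(config)
    return combined_feature_matrix(smiles_list, schedule=schedule_from_config(config))


def predict_micromolar(bioactivity: float) -> float:
    """Predicted bioactivity back to a molar-scale concentration in uM.

    The exact monotone inverse of the -log10 transform: a predicted
    bioactivity of 6.0 corresponds to 1.0 uM.
    """
    return 10.0 ** (-bioactivity) * 1.0e6


def run_pipeline(
    config: dict | None = None,
    dataset: Sequence[CuratedLigand] | None = None,
    output_dir: str | Path | None = None,
    select_features: bool = False,
) -> dict:
    """Execute the full modelling workflow.

    Input is either ``dataset`` (already-curated ligands) or a ligand
    table at ``config["input"]``.  Returns a result dict with the split
    plan, per-algorithm CV reports, the chosen model, blind-test and
    outlier-trimmed metrics; when ``output_dir`` is given, artifacts
    (curated table, feature table, split plan, predictions, model,
    manifest) are also written there.
    """
    config = resolve_config(config)
    seed = int(config["seed"])

    if dataset is None:
        if "input" not in config:
            raise ConfigError("config key 'input' (ligand table path) is required when no dataset is passed")
        records, rejections = read_ligand_table(config["input"], delimiter=config["delimiter"])
        dataset = curate_dataset(
            records,
            max_spread=config["max_spread"],
            statistic=config["aggregate_statistic"],
        )
    else:
        rejections = []
        dataset = list(dataset)

    smiles = [lig.smiles for lig in dataset]
    y = np.asarray([lig.bioactivity for lig in dataset])
    features = featurize(smiles, config)

    plan = make_split_plan(
        smiles,
        y,
        ks=(config["cv_folds"],),
        blind_fraction=config["blind_fraction"],
        similarity_threshold=config["similarity_threshold"],
        n_bits=config["fingerprint_bits"],
        n_bins=config["stratify_bins"],
        seed=seed,
    )
    tr, bl = plan.train_indices, plan.blind_indices
    X_train, X_blind = features.iloc[tr], features.iloc[bl]
    y_train, y_blind = y[tr], y[bl]
    folds = plan.folds[config["cv_folds"]]

    n_est = config["n_estimators"]
    cv_reports: dict[str, MetricsReport] = {}
    for alg in config["algorithms"]:
        report, _, _ = cross_validate(X_train, y_train, alg, folds, n_est, set_label=f"cv-{alg}")
        cv_reports[alg] = report
    best_alg, best_cv = select_best_model(cv_reports)

    selected = None
    if select_features:
        selected, _trace = greedy_forward_selection(X_train, y_train, best_alg, folds, n_estimators=n_est)
        X_train_fit, X_blind_fit = X_train[selected], X_blind[selected]
    else:
        X_train_fit, X_blind_fit = X_train, X_blind

    model = train_model(X_train_fit, y_train, best_alg, n_est)
    model.selection_order = selected
    blind_pred = model.predict(X_blind_fit)
    blind_report = evaluate(blind_pred, y_blind, set_label="blind")
    if len(y_blind) >= 10:
        trimmed_report, trimmed_ids = outlier_trimmed_metrics(
            blind_pred,
            y_blind,
            trim_fraction=config["trim_fraction"],
            identities=[smiles[i] for i in bl],
        )
    else:  # too few blind points for a meaningful 10% trim
        trimmed_report, trimmed_ids = None, []

    result = {
        "config": config,
        "config_hash": config_hash(config),
        "seed": seed,
        "dataset": dataset,
        "n_ligands": len(dataset),
        "n_rejected_rows": len(rejections),
        "features": features,
        "split_plan": plan,
        "cv_reports": cv_reports,
        "best_algorithm": best_alg,
        "best_cv_report": best_cv,
        "selected_features": selected,
        "model": model,
        "blind_predictions": blind_pred,
        "blind_report": blind_report,
        "trimmed_report": trimmed_report,
        "trimmed_ligands": trimmed_ids,
    }
    if output_dir is not None:
        _write_artifacts(result, Path(output_dir), config)
    return result


def _write_artifacts(result: dict, out: Path, config: dict) -> None:
    out.mkdir(parents=True, exist_ok=True)
    write_curated_table(result["dataset"], out / "curated.csv", delimiter=config["delimiter"])
    result["features"].rename_axis("smiles").to_csv(out / "features.csv", sep=config["delimiter"])
    result["split_plan"].to_frame().to_csv(out / "split_plan.csv", sep=config["delimiter"], index=False)

    plan = result["split_plan"]
    bl = plan.blind_indices
    smiles = [lig.smiles for lig in result["dataset"]]
    y = [lig.bioactivity for lig in result["dataset"]]
    preds = pd.DataFrame(
        {
            "smiles": [smiles[i] for i in bl],
            "target": [y[i] for i in bl],
            "prediction": result["blind_predictions"],
            "set_label": "blind",
        }
    )
    preds["residual"] = preds["prediction"] - preds["target"]
    preds.to_csv(out / "predictions.csv", sep=config["delimiter"], index=False)

    joblib.dump(result["model"], out / "model.joblib")

    manifest = {
        "config": {k: v for k, v in config.items()},
        "config_hash": result["config_hash"],
        "seed": result["seed"],
        "n_ligands": result["n_ligands"],
        "n_rejected_rows": result["n_rejected_rows"],
        "best_algorithm": result["best_algorithm"],
        "selected_features": result["selected_features"],
        "max_cross_tanimoto": plan.max_cross_tanimoto,
        "cv_reports": {a: r.to_dict() for a, r in result["cv_reports"].items()},
        "blind_report": result["blind_report"].to_dict(),
        "trimmed_report": result["trimmed_report"].to_dict() if result["trimmed_report"] else None,
        "trimmed_ligands": result["trimmed_ligands"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
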