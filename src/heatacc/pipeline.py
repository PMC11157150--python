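"""High-level pipeline stages chained by the CLI and the analysis drivers.

``train_pipeline`` runs preprocess → features → select → classify on a
labelled burst file; ``analyze_pipeline`` runs predict → consolidate →
weather join → afternoon heat models and hot/cool diel models on an
unlabelled burst file.  Every run writes a provenance record (inputs,
options, seed) next to its outputs so identical configuration yields
identical, auditable results.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

from . import budget as bud
from . import classify as clf
from . import ethogram as eth
from . import features as feat
from . import preprocess as prep
from . import select as sel
from . import smooth_models as sm
from . import thermal as th
from .io import BurstDialect, read_bursts, read_labelled_bursts, read_weather

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """An upstream pipeline stage failed; the stage name is in the message."""


def _provenance(out_dir: Path, stage: str, options: dict) -> None:
    (out_dir / f"{stage}_provenance.json").write_text(
        json.dumps({"stage": stage, "options": options}, indent=2, default=str)
    )


def train_pipeline(
    training_path: str | Path,
    out_dir: str | Path,
    dialect: BurstDialect,
    k: int = sel.DEFAULT_K,
    threshold: float = sel.DEFAULT_CORRELATION_THRESHOLD,
    folds: int = 5,
    odba_window: int = feat.DEFAULT_ODBA_WINDOW,
    hp: clf.Hyperparams = clf.DEFAULT_HYPERPARAMS,
    seed: int = 0,
) -> dict:
    """Label file → fitted model + selection result + confusion report files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        labelled, issues = read_labelled_bursts(training_path, dialect)
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError(f"io: {exc}") from exc
    if issues:
        logger.warning("io: %d rows failed validation", len(issues))
    if not labelled:
        raise StageError("io: no valid labelled bursts")

    centered = [prep.center(lb.burst) for lb in labelled]
    labels = [lb.behaviour for lb in labelled]
    matrix = feat.feature_matrix(centered, window=odba_window)
    matrix.to_csv(out_dir / "training_features.csv", index=False)

    selection = sel.select_features(
        matrix, labels, k=k, threshold=threshold, cv_folds=folds, hp=hp, seed=seed
    )
    selection.to_frame().to_csv(out_dir / "selection.csv", index=False)

    model = clf.train(matrix, labels, list(selection.features), hp=hp, seed=seed)
    model.save(str(out_dir / "model.json"), str(out_dir / "model_meta.json"))

    report = clf.cross_validate(
        matrix, labels, list(selection.features), hp=hp, folds=folds, seed=seed
    )
    report.to_frame().to_csv(out_dir / "confusion_matrix.csv")
    summary = {
        "accuracy": report.accuracy,
        "accuracy_ci": report.accuracy_ci,
        "selected_features": list(selection.features),
        "contributions": list(selection.contributions),
        "n_bursts": len(labelled),
        "n_parse_issues": len(issues),
    }
    (out_dir / "train_summary.json").write_text(json.dumps(summary, indent=2))
    _provenance(
        out_dir,
        "train",
        {
            "training": str(training_path),
            "k": k,
            "threshold": threshold,
            "folds": folds,
            "odba_window": odba_window,
            "hp": dataclasses.asdict(hp),
            "seed": seed,
        },
    )
    return summary


def analyze_pipeline(
    model_dir: str | Path,
    bursts_path: str | Path,
    weather_path: str | Path,
    out_dir: str | Path,
    dialect: BurstDialect,
    blackglobe_coeffs: dict | None = th.DEFAULT_BLACKGLOBE_COEFFS,
    utc_offset_hours: float = bud.DEFAULT_UTC_OFFSET_HOURS,
    min_n: int = bud.DEFAULT_MIN_RECORDINGS,
    n_extreme_days: int = th.DEFAULT_N_EXTREME_DAYS,
    odba_window: int = feat.DEFAULT_ODBA_WINDOW,
    alpha: float = sm.DEFAULT_ALPHA,
    skip_diel: bool = False,
) -> dict:
    """Model + unlabelled bursts + weather → budget cells and model reports."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model_dir = Path(model_dir)
    try:
        model = clf.FittedClassifier.load(
            str(model_dir / "model.json"), str(model_dir / "model_meta.json")
        )
    except Exception as exc:
        raise StageError(f"model: {exc}") from exc
    try:
        bursts, issues = read_bursts(bursts_path, dialect)
    except Exception as exc:
        raise StageError(f"io: {exc}") from exc
    try:
        weather = read_weather(weather_path)
    except Exception as exc:
        raise StageError(f"weather: {exc}") from exc

    centered = [prep.center(b) for b in bursts]
    matrix = feat.feature_matrix(centered, window=odba_window)
    matrix["behaviour"] = clf.predict(model, matrix)

    records, excl_report = eth.consolidate_records(matrix)
    logger.info(
        "ethogram: excluded %d of %d records (%.2f%%)",
        excl_report.n_excluded,
        excl_report.n_input,
        100 * excl_report.excluded_fraction,
    )

    thermal_series = th.add_blackglobe(weather, blackglobe_coeffs)
    records = bud.join_weather(records, thermal_series)
    records = bud.add_local_time(records, utc_offset_hours)

    afternoon = bud.afternoon_filter(records)
    cells = bud.time_budget(afternoon)
    cells.to_csv(out_dir / "afternoon_budget_cells.csv", index=False)
    odba_cells = bud.mean_odba_cells(afternoon, min_n=min_n)
    odba_cells.to_csv(out_dir / "afternoon_odba_cells.csv", index=False)

    heat_reports = {}
    for behaviour in eth.ANALYSIS_CATEGORIES:
        try:
            fit = sm.fit_heat_model(cells, behaviour, alpha=alpha)
            (out_dir / f"heat_{behaviour}_terms.txt").write_text(fit.report())
            heat_reports[behaviour] = {
                "terms": fit.terms.to_dict("records"),
                "concurvity": fit.concurvity,
            }
        except ValueError as exc:
            logger.warning("heat model for %s skipped: %s", behaviour, exc)

    diel_reports = {}
    if not skip_diel:
        dmax = th.daily_max(bud.add_local_time(thermal_series, utc_offset_hours))
        try:
            extreme = th.select_extreme_days(dmax, n=n_extreme_days)
            extreme.to_frame().to_csv(out_dir / "extreme_days.csv", index=False)
            diel_cells = bud.diel_budget(records, extreme)
            diel_cells.to_csv(out_dir / "diel_budget_cells.csv", index=False)
            for behaviour in eth.ANALYSIS_CATEGORIES:
                fit = sm.fit_diel_model(diel_cells, behaviour, alpha=alpha)
                (out_dir / f"diel_{behaviour}_terms.txt").write_text(fit.report())
                diel_reports[behaviour] = dict(fit.extras)
        except ValueError as exc:
            logger.warning("diel comparison skipped: %s", exc)

    summary = {
        "n_predictions": int(excl_report.n_input),
        "excluded_fraction": excl_report.excluded_fraction,
        "n_afternoon_cells": int(len(cells)),
        "n_odba_cells": int(len(odba_cells)),
        "heat_models": heat_reports,
        "diel_models": diel_reports,
        "n_parse_issues": len(issues),
    }
    (out_dir / "analyze_summary.json").write_text(
        json.dumps(summary, indent=2, default=float)
    )
    _provenance(
        out_dir,
        "analyze",
        {
            "model_dir": str(model_dir),
            "bursts": str(bursts_path),
            "weather": str(weather_path),
            "utc_offset_hours": utc_offset_hours,
            "min_n": min_n,
            "n_extreme_days": n_extreme_days,
            "alpha": alpha,
        },
    )
    return summary
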