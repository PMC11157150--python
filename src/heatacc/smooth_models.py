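"""The two penalized-spline mixed models of the heat-response analysis.

*Afternoon heat model* — per behaviour, the proportion of time allocated
to it (or its mean ODBA) as a function of species and the species-specific
smooths of blackglobe temperature and hour of the afternoon, plus month as
a factor (three levels — a smooth over three points is degenerate) and
random intercepts per individual.  Proportions use a logit link with
quasi-binomial variance weighted by the number of records behind each
cell; mean ODBA uses an identity link with constant variance.

*Diel model* — per behaviour, the proportion of time over the full
24-hour cycle as a function of a cyclic smooth of hour, the hot-day/
cool-day factor, a hot-day contrast smooth of hour (the interaction), and
random intercepts per individual.  Diel patterns differ between hot and
cool days when the interaction smooth is significant; the overall
24-hour activity level differs when the day-class intercept contrast is
significant.  The percentage difference of 24-h means is the ratio of the
hot and cool mean predicted proportions over an hourly grid, minus one.

Significance throughout is assessed at alpha = .05, and each fitted model
carries its worst-case concurvity diagnostics (values at or above 0.8 are
flagged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gam import (
    AdditiveFit,
    AdditiveModel,
    Factor,
    RandomIntercept,
    Spline,
)

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
DEFAULT_K_BLACKGLOBE = 10
DEFAULT_K_HOUR = 8
CONCURVITY_WARN = 0.8


@dataclass
class SmoothFit:
    """A fitted model with term-wise significance and diagnostics."""

    response: str
    family: str
    terms: pd.DataFrame  # term, edf, ref_df, statistic, p_value
    parametric: pd.DataFrame  # term, estimate, se, t, p_value
    concurvity: dict[str, float]
    alpha: float
    fit: AdditiveFit
    extras: dict = field(default_factory=dict)

    def term_p(self, term: str) -> float:
        row = self.terms[self.terms["term"] == term]
        if not len(row):
            raise KeyError(f"no smooth term {term!r}")
        return float(row["p_value"].iloc[0])

    def contrast_p(self, term: str) -> float:
        row = self.parametric[self.parametric["term"] == term]
        if not len(row):
            raise KeyError(f"no parametric term {term!r}")
        return float(row["p_value"].iloc[0])

    def report(self) -> str:
        lines = [
            f"response: {self.response}   family: {self.family}   "
            f"alpha: {self.alpha}",
            "",
            "smooth terms (edf, ref.df, F, p):",
            self.terms.to_string(index=False, float_format=lambda v: f"{v:.4f}"),
            "",
            "parametric terms:",
            self.parametric.to_string(index=False, float_format=lambda v: f"{v:.4f}"),
            "",
            "worst-case concurvity: "
            + ", ".join(f"{k}={v:.3f}" for k, v in self.concurvity.items()),
        ]
        return "\n".join(lines)


def _finish(model: AdditiveModel, data, y, w, response: str, extras=None, alpha=DEFAULT_ALPHA):
    fitted = model.fit(data, y, weights=w)
    rows = []
    for b in fitted.blocks:
        if type(b.spec).__name__ == "Spline":
            edf, ref_df, fstat, p = fitted.smooth_test(b.name)
            rows.append(
                {"term": b.name, "edf": edf, "ref_df": ref_df, "statistic": fstat, "p_value": p}
            )
        elif type(b.spec).__name__ == "RandomIntercept":
            rows.append(
                {
                    "term": b.name,
                    "edf": fitted.term_edf(b.name),
                    "ref_df": float(b.sl.stop - b.sl.start),
                    "statistic": np.nan,
                    "p_value": np.nan,
                }
            )
    parametric = pd.concat(
        [
            fitted.coef_table(b.name)
            for b in fitted.blocks
            if type(b.spec).__name__ in ("Intercept", "Factor", "Linear")
            and b.sl.stop > b.sl.start
        ],
        ignore_index=True,
    )
    conc = concurvity(fitted)
    return SmoothFit(
        response=response,
        family=model.family,
        terms=pd.DataFrame(rows),
        parametric=parametric,
        concurvity=conc,
        alpha=alpha,
        fit=fitted,
        extras=extras or {},
    )


def fit_heat_model(
    cells: pd.DataFrame,
    behaviour: str,
    species_col: str | None = None,
    response: str = "proportion",
    k_blackglobe: int = DEFAULT_K_BLACKGLOBE,
    k_hour: int = DEFAULT_K_HOUR,
    alpha: float = DEFAULT_ALPHA,
) -> SmoothFit:
    """Afternoon heat-response model for one behaviour.

    ``cells`` is a time-budget frame (per-category proportion columns plus
    ``n_records``) when ``response="proportion"``, or a mean-ODBA cell
    frame (``category``, ``mean_odba``, ``n_recordings``) when
    ``response="mean_odba"``.  With a ``species_col`` holding two or more
    levels, the blackglobe and hour smooths are fitted per species
    ("by"-smooths); for a single species they collapse to plain smooths.
    """
    if response == "proportion":
        data = cells.copy()
        y = data[behaviour].to_numpy(float)
        w = data["n_records"].to_numpy(float)
        family = "quasibinomial"
    elif response == "mean_odba":
        data = cells[cells["category"] == behaviour].reset_index(drop=True).copy()
        y = data["mean_odba"].to_numpy(float)
        w = data["n_recordings"].to_numpy(float)
        w = w / w.mean()
        family = "gaussian"
    else:
        raise ValueError("response must be 'proportion' or 'mean_odba'")
    if len(data) < 20:
        raise ValueError(f"need >= 20 cells, have {len(data)}")

    k_bg = min(k_blackglobe, data["blackglobe_bin"].nunique())
    k_hr = min(k_hour, data["hour"].nunique())
    terms: list = []
    levels = sorted(data[species_col].unique()) if species_col else []
    if species_col and len(levels) >= 2:
        terms.append(Factor(species_col))
        for lev in levels:
            terms.append(Spline("blackglobe_bin", k=max(k_bg, 4), by=(species_col, lev)))
            terms.append(Spline("hour", k=max(k_hr, 4), by=(species_col, lev)))
    else:
        terms.append(Spline("blackglobe_bin", k=max(k_bg, 4)))
        terms.append(Spline("hour", k=max(k_hr, 4)))
    if data["month"].nunique() > 1:
        data["month"] = data["month"].astype(str)
        terms.append(Factor("month"))
    terms.append(RandomIntercept("individual_id"))

    model = AdditiveModel(terms, family=family)
    fit = _finish(model, data, y, w, response=f"{behaviour} ({response})", alpha=alpha)
    high = {k: v for k, v in fit.concurvity.items() if v >= CONCURVITY_WARN}
    if high:
        logger.warning("concurvity at or above %.1f: %s", CONCURVITY_WARN, high)
    return fit


def fit_diel_model(
    diel_cells: pd.DataFrame,
    behaviour: str,
    k_hour: int = DEFAULT_K_HOUR,
    alpha: float = DEFAULT_ALPHA,
) -> SmoothFit:
    """Hot/cool-day diel model for one behaviour.

    Requires both day classes and at least 12 distinct hours of coverage.
    The returned fit's ``extras`` carry the interaction and intercept
    contrast p-values and ``pct_difference_24h`` — the percentage
    difference of the 24-h mean predicted proportion on hot relative to
    cool days.
    """
    data = diel_cells.copy()
    classes = set(data["day_class"].unique())
    if classes != {"hot", "cool"}:
        raise ValueError(f"need both day classes, have {sorted(classes)}")
    if data["hour"].nunique() < 12:
        raise ValueError("need >= 12 distinct hours of coverage")
    y = data[behaviour].to_numpy(float)
    w = data["n_records"].to_numpy(float)

    terms = [
        Factor("day_class"),
        Spline("hour", k=k_hour, cyclic=True, period=24.0),
        Spline("hour", k=k_hour, cyclic=True, period=24.0, by=("day_class", "hot"),
               label="s(hour):hot"),
        RandomIntercept("individual_id"),
    ]
    model = AdditiveModel(terms, family="quasibinomial")
    fit = _finish(model, data, y, w, response=f"{behaviour} (diel proportion)", alpha=alpha)

    grid_hours = np.arange(24)
    preds = {}
    for cls in ("hot", "cool"):
        grid = pd.DataFrame(
            {
                "hour": grid_hours,
                "day_class": cls,
                "individual_id": data["individual_id"].iloc[0],
            }
        )
        preds[cls] = fit.fit.predict(grid, response=True)
    mean_hot, mean_cool = preds["hot"].mean(), preds["cool"].mean()
    fit.extras.update(
        {
            "interaction_p": fit.term_p("s(hour):hot"),
            "intercept_contrast_p": fit.contrast_p("day_class[hot]"),
            "mean_24h_hot": float(mean_hot),
            "mean_24h_cool": float(mean_cool),
            "pct_difference_24h": float((mean_hot - mean_cool) / mean_cool * 100.0),
        }
    )
    return fit


def concurvity(fit: AdditiveFit) -> dict[str, float]:
    """Worst-case concurvity per smooth; warns when any is >= 0.8."""
    values = fit.concurvity()
    high = {k: v for k, v in values.items() if v >= CONCURVITY_WARN}
    if high:
        logger.warning("concurvity at or above %.1f: %s", CONCURVITY_WARN, high)
    return values
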