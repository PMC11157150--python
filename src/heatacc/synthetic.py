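"""Synthetic collar data with the statistical structure the analysis assumes.

Three generators cover every pipeline stage without any field download:

- :func:`simulate_burst` / :func:`make_training_set` — labelled tri-axial
  bursts.  Each behaviour is a phenomenological signal model: a static
  posture offset per axis (gravity on z, head position on x), one periodic
  component (gait/chewing frequency, amplitude, axis loading) and Gaussian
  sensor noise, optionally rotated in the (y, z) plane to emulate collar
  rotation about the neck.  The defaults are chosen to make the twelve
  ethogram behaviours pairwise distinguishable in the 19-feature space —
  the regime in which a feature-based classifier is expected to work.
- :func:`simulate_timeline` — per-individual 5-minute behaviour sequences
  over many days, drawn from a multinomial whose log-odds move with hour
  of day and blackglobe temperature, with first-order persistence, plus a
  matching hourly weather series (sinusoidal diel temperature cycle,
  day-level hot/cool variation, daytime solar arc, humidity inversely
  tracking temperature).  Planted effects (temperature slopes, hot-day
  suppression with or without nocturnal compensation) are written to a
  ground-truth record so recovery tests never re-derive truth from the
  generator internals.
- :func:`make_fixture_suite` — deterministic delimited-text fixtures
  (labelled training set, 2-individual 20-day scenario, weather file)
  for tests and walkthroughs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .ethogram import ANALYSIS_CATEGORIES, ETHOGRAM_LABELS
from .io import AccBurst, BurstDialect, LabeledBurst, write_bursts, write_weather
from .thermal import DEFAULT_BLACKGLOBE_COEFFS, blackglobe

DEFAULT_FS = 33.3
DEFAULT_N_SAMPLES = 110
TICKS_PER_DAY = 288  # one burst every 5 min


@dataclass(frozen=True)
class BehaviourSignal:
    """Signal model of one behaviour: posture + one periodic component + noise."""

    posture: tuple[float, float, float]  # centered counts (x, y, z)
    freq: float  # Hz; 0 = no periodicity
    amp: float  # counts
    loading: tuple[float, float, float] = (1.0, 0.3, 0.5)
    noise_sd: float = 30.0
    rotate_yz: bool = True  # draw a collar-rotation angle per burst


#: Default, pairwise-distinguishable signal models for the 12 behaviours.
DEFAULT_SIGNAL_MODELS: dict[str, BehaviourSignal] = {
    "sleeping": BehaviourSignal((-250, 50, 520), 0.0, 0.0, noise_sd=5.0),
    "low-activity": BehaviourSignal((0, 0, 620), 0.0, 0.0, noise_sd=20.0),
    "ruminating": BehaviourSignal((30, 0, 600), 1.0, 70.0, (0.0, 0.7, 0.7), 12.0),
    "browsing": BehaviourSignal((350, 0, 450), 0.8, 110.0, (1.0, 0.2, 0.3), 40.0),
    "grazing": BehaviourSignal((-420, 0, 380), 0.5, 70.0, (1.0, 0.3, 0.2), 80.0),
    "foraging": BehaviourSignal((-200, 0, 450), 1.2, 130.0, (1.0, 0.2, 0.4), 50.0),
    "walking": BehaviourSignal((80, 0, 480), 1.5, 260.0, (1.0, 0.3, 0.5), 35.0),
    "trotting": BehaviourSignal((100, 0, 450), 2.5, 520.0, (1.0, 0.4, 0.7), 60.0),
    "running": BehaviourSignal((120, 0, 400), 3.5, 900.0, (1.0, 0.5, 0.8), 90.0),
    "drinking": BehaviourSignal((-520, 0, 350), 0.3, 45.0, (1.0, 0.2, 0.1), 18.0),
    "salt-licking": BehaviourSignal((-460, 60, 380), 2.0, 60.0, (0.3, 1.0, 0.2), 25.0),
    "grooming": BehaviourSignal((150, 120, 420), 1.8, 130.0, (0.2, 1.0, 0.4), 35.0),
}

#: Ethogram labels drawn when the timeline emits each analysis category.
_CATEGORY_SUBLABELS: dict[str, tuple[tuple[str, ...], tuple[float, ...]]] = {
    "browsing": (("browsing",), (1.0,)),
    "grazing": (("grazing",), (1.0,)),
    "walking": (("walking", "foraging"), (0.8, 0.2)),
    "ruminating": (("ruminating",), (1.0,)),
    "resting": (("low-activity", "sleeping"), (0.7, 0.3)),
}

_EXCLUDED_LABELS = ("drinking", "salt-licking", "grooming", "trotting", "running")

#: Typical ODBA level (counts) emitted per analysis category by the timeline.
_CATEGORY_ODBA: dict[str, tuple[float, float]] = {  # (mean, sd)
    "browsing": (70.0, 15.0),
    "grazing": (90.0, 20.0),
    "walking": (150.0, 30.0),
    "ruminating": (25.0, 6.0),
    "resting": (8.0, 3.0),
}


def _signal_matrix(
    behaviour: str,
    model: dict[str, BehaviourSignal],
    count: int,
    fs: float,
    n: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centered (count, n) signal per axis for ``count`` bursts of one behaviour."""
    if behaviour not in model:
        raise KeyError(f"no signal model for behaviour {behaviour!r}")
    sig = model[behaviour]
    t = np.arange(n) / fs
    phase = rng.uniform(0, 2 * np.pi, size=(count, 1))
    wave = np.sin(2 * np.pi * sig.freq * t[None, :] + phase) if sig.freq > 0 else 0.0
    axes = []
    for a in range(3):
        axes.append(
            sig.posture[a]
            + sig.amp * sig.loading[a] * (wave if sig.freq > 0 else 0.0)
            + rng.normal(0, sig.noise_sd, size=(count, n))
        )
    x, y, z = axes
    if sig.rotate_yz:
        theta = rng.uniform(0, 2 * np.pi, size=(count, 1))
        y, z = (
            y * np.cos(theta) - z * np.sin(theta),
            y * np.sin(theta) + z * np.cos(theta),
        )
    return x, y, z


def _to_counts(sig: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(2048 + sig), 0, 4095).astype(np.int64)


def simulate_burst(
    behaviour: str,
    model: dict[str, BehaviourSignal] = DEFAULT_SIGNAL_MODELS,
    fs: float = DEFAULT_FS,
    n: int = DEFAULT_N_SAMPLES,
    seed: int | np.random.Generator = 0,
    individual_id: str = "sim",
    timestamp: pd.Timestamp | None = None,
) -> LabeledBurst:
    """One labelled synthetic burst; deterministic per seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x, y, z = _signal_matrix(behaviour, model, 1, fs, n, rng)
    return LabeledBurst(
        burst=AccBurst(
            individual_id=individual_id,
            timestamp=timestamp or pd.Timestamp("2020-10-01T06:00:00Z"),
            fs=fs,
            x_raw=_to_counts(x[0]),
            y_raw=_to_counts(y[0]),
            z_raw=_to_counts(z[0]),
        ),
        behaviour=behaviour,
    )


def make_training_set(
    n_per_behaviour: int = 170,
    behaviours: tuple[str, ...] = ETHOGRAM_LABELS,
    model: dict[str, BehaviourSignal] = DEFAULT_SIGNAL_MODELS,
    fs: float = DEFAULT_FS,
    n: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
    individual_id: str = "train01",
) -> list[LabeledBurst]:
    """A labelled burst set with ``n_per_behaviour`` bursts per behaviour."""
    rng = np.random.default_rng(seed)
    start = pd.Timestamp("2020-09-01T06:00:00Z")
    out: list[LabeledBurst] = []
    i = 0
    for beh in behaviours:
        x, y, z = _signal_matrix(beh, model, n_per_behaviour, fs, n, rng)
        for j in range(n_per_behaviour):
            out.append(
                LabeledBurst(
                    burst=AccBurst(
                        individual_id=individual_id,
                        timestamp=start + pd.Timedelta(seconds=30 * i),
                        fs=fs,
                        x_raw=_to_counts(x[j]),
                        y_raw=_to_counts(y[j]),
                        z_raw=_to_counts(z[j]),
                    ),
                    behaviour=beh,
                )
            )
            i += 1
    return out


@dataclass
class ScenarioConfig:
    """Study conditions for a simulated deployment.

    Defaults mirror the collar schedule (one 3.3-s burst at 33.3 Hz every
    5 min) over a 20-day window inside the hot season, with a diel
    temperature cycle, day-to-day variation in daily maximum temperature,
    and temperature-dependent behaviour allocation: grazing is suppressed
    and resting/ruminating promoted as blackglobe temperature rises.
    """

    name: str = "springbok-like"
    n_individuals: int = 2
    n_days: int = 20
    start: str = "2020-10-01"  # local date
    utc_offset_hours: float = 2.0
    fs: float = DEFAULT_FS
    n_samples: int = DEFAULT_N_SAMPLES
    tick_minutes: int = 5
    # behaviour allocation (log-odds of the 5 analysis categories)
    base_logits: dict = field(
        default_factory=lambda: {
            "browsing": -0.4,
            "grazing": 0.6,
            "walking": -0.5,
            "ruminating": 0.1,
            "resting": 0.4,
        }
    )
    #: (amplitude, peak hour): diel modulation amp*cos(2*pi*(h-peak)/24)
    diel_curves: dict = field(
        default_factory=lambda: {
            "browsing": (0.5, 9.0),
            "grazing": (0.7, 8.0),
            "walking": (0.4, 7.0),
            "ruminating": (0.4, 22.0),
            "resting": (0.7, 1.0),
        }
    )
    #: log-odds change per deg C blackglobe above bg_ref
    temp_slopes: dict = field(
        default_factory=lambda: {
            "browsing": 0.01,
            "grazing": -0.06,
            "walking": 0.0,
            "ruminating": 0.03,
            "resting": 0.04,
        }
    )
    bg_ref: float = 45.0
    persistence: float = 0.6
    excluded_rate: float = 0.02
    day_max_range: tuple[float, float] = (29.0, 41.0)
    diel_temp_span: float = 14.0  # daily max minus daily min air temperature
    #: hot-day planting: None, "compensated" (daytime suppression with full
    #: nocturnal compensation) or "flat" (uniform multiplier)
    hot_day_effect: str | None = None
    hot_day_category: str = "grazing"
    hot_day_factor: float = 0.5
    hot_day_window: tuple[int, int] = (10, 18)  # local hours [lo, hi)
    seed: int = 0


def _weather_frame(cfg: ScenarioConfig, day_max: np.ndarray) -> pd.DataFrame:
    """Hourly weather series for the scenario (timestamps in UTC)."""
    hours = np.arange(cfg.n_days * 24)
    day = hours // 24
    h = hours % 24
    tmax = day_max[day]
    tmin = tmax - cfg.diel_temp_span
    air = tmin + (tmax - tmin) * (1 + np.cos(2 * np.pi * (h - 15) / 24)) / 2
    solar = np.maximum(0.0, 950.0 * np.sin(np.pi * (h - 6) / 12)) * ((h >= 6) & (h <= 18))
    rh = np.clip(55.0 - 1.2 * (air - 28.0), 5.0, 95.0)
    local = pd.Timestamp(cfg.start) + pd.to_timedelta(hours, unit="h")
    ts = (local - pd.Timedelta(hours=cfg.utc_offset_hours)).tz_localize("UTC")
    return pd.DataFrame(
        {"timestamp": ts, "air_temp": air, "solar": solar, "rh": rh}
    )


def _category_probs(cfg: ScenarioConfig, bg_by_day_hour: np.ndarray) -> np.ndarray:
    """(n_days, 24, 5) category probabilities, with any hot-day planting applied."""
    cats = list(ANALYSIS_CATEGORIES)
    h = np.arange(24)
    logits = np.empty((cfg.n_days, 24, len(cats)))
    for ci, c in enumerate(cats):
        amp, peak = cfg.diel_curves[c]
        logits[:, :, ci] = (
            cfg.base_logits[c]
            + amp * np.cos(2 * np.pi * (h[None, :] - peak) / 24)
            + cfg.temp_slopes[c] * (bg_by_day_hour - cfg.bg_ref)
        )
    p = np.exp(logits - logits.max(axis=2, keepdims=True))
    p /= p.sum(axis=2, keepdims=True)

    if cfg.hot_day_effect is not None:
        ci = cats.index(cfg.hot_day_category)
        day_rank = np.argsort(np.argsort(bg_by_day_hour.max(axis=1)))
        hot_days = day_rank >= cfg.n_days // 2  # hotter half of days
        lo, hi = cfg.hot_day_window
        day_hours = (h >= lo) & (h < hi)
        m = np.ones(24)
        if cfg.hot_day_effect == "flat":
            m[:] = cfg.hot_day_factor
        elif cfg.hot_day_effect == "compensated":
            pt = p[hot_days][:, :, ci].mean(axis=0)
            night = ~day_hours
            c_night = (pt.sum() - cfg.hot_day_factor * pt[day_hours].sum()) / pt[
                night
            ].sum()
            m[day_hours] = cfg.hot_day_factor
            m[night] = c_night
        else:
            raise ValueError(f"unknown hot_day_effect {cfg.hot_day_effect!r}")
        for d in np.flatnonzero(hot_days):
            pt = p[d, :, ci] * m
            pt = np.clip(pt, 1e-6, 0.95)
            scale = (1 - pt) / (1 - p[d, :, ci])
            for cj in range(len(cats)):
                if cj != ci:
                    p[d, :, cj] *= scale
            p[d, :, ci] = pt
        p /= p.sum(axis=2, keepdims=True)
    return p


def simulate_timeline(
    cfg: ScenarioConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate per-tick behaviours and weather for a whole deployment.

    Returns ``(timeline, weather, truth)``: the timeline has one row per
    individual and 5-min tick (UTC timestamp, true category, emitted
    ethogram label, synthetic per-burst ODBA), the weather series is
    hourly, and ``truth`` records every planted parameter so recovery
    tests read it rather than the generator internals.

    Behaviours follow a first-order chain: with probability
    ``persistence`` the previous tick's category repeats, otherwise a
    fresh draw is made from the (hour, temperature)-dependent multinomial
    — the stationary distribution at fixed conditions equals that
    multinomial.
    """
    rng = np.random.default_rng(cfg.seed)
    day_max = rng.uniform(*cfg.day_max_range, size=cfg.n_days)
    weather = _weather_frame(cfg, day_max)
    bg = blackglobe(
        weather["air_temp"].to_numpy(),
        weather["solar"].to_numpy(),
        weather["rh"].to_numpy(),
        DEFAULT_BLACKGLOBE_COEFFS,
    )
    bg_by_day_hour = bg.reshape(cfg.n_days, 24)
    probs = _category_probs(cfg, bg_by_day_hour)

    cats = list(ANALYSIS_CATEGORIES)
    ticks_per_day = 24 * 60 // cfg.tick_minutes
    n_ticks = cfg.n_days * ticks_per_day
    tick_hours = (np.arange(n_ticks) * cfg.tick_minutes // 60) % 24
    tick_days = np.arange(n_ticks) * cfg.tick_minutes // (24 * 60)
    local = pd.Timestamp(cfg.start) + pd.to_timedelta(
        np.arange(n_ticks) * cfg.tick_minutes, unit="m"
    )
    ts_utc = (local - pd.Timedelta(hours=cfg.utc_offset_hours)).tz_localize("UTC")

    rows_ind, rows_cat = [], []
    for ind in range(cfg.n_individuals):
        p_seq = probs[tick_days, tick_hours]  # (n_ticks, 5)
        u_fresh = rng.random(n_ticks)
        u_keep = rng.random(n_ticks)
        cdf = np.cumsum(p_seq, axis=1)
        draws = (u_fresh[:, None] > cdf).sum(axis=1)
        seq = np.empty(n_ticks, dtype=np.int64)
        prev = draws[0]
        for t in range(n_ticks):
            if t and u_keep[t] < cfg.persistence:
                seq[t] = prev
            else:
                seq[t] = draws[t]
            prev = seq[t]
        rows_ind.append(np.full(n_ticks, f"sim{ind + 1:02d}"))
        rows_cat.append(seq)

    individual = np.concatenate(rows_ind)
    cat_idx = np.concatenate(rows_cat)
    timestamps = np.tile(ts_utc, cfg.n_individuals)
    category = np.array(cats, dtype=object)[cat_idx]

    # emit ethogram labels: mostly category sub-labels, a little of the rest
    n_total = len(category)
    label = np.empty(n_total, dtype=object)
    for c, (subs, w) in _CATEGORY_SUBLABELS.items():
        mask = category == c
        label[mask] = rng.choice(subs, size=int(mask.sum()), p=w)
    excl = rng.random(n_total) < cfg.excluded_rate
    label[excl] = rng.choice(_EXCLUDED_LABELS, size=int(excl.sum()))

    odba_mean = np.array([_CATEGORY_ODBA[c][0] for c in cats])
    odba_sd = np.array([_CATEGORY_ODBA[c][1] for c in cats])
    odba = np.maximum(
        rng.normal(odba_mean[cat_idx], odba_sd[cat_idx]), 0.0
    )

    timeline = pd.DataFrame(
        {
            "individual_id": individual,
            "timestamp": timestamps,
            "category": category,
            "behaviour": label,
            "odba": odba,
        }
    )
    truth = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(cfg).items()
        },
        "day_max_air_temp": day_max.tolist(),
        "temp_slopes": dict(cfg.temp_slopes),
        "hot_day_effect": cfg.hot_day_effect,
        "hot_day_factor": cfg.hot_day_factor,
        "expected_pct_difference": (
            (cfg.hot_day_factor - 1.0) * 100.0 if cfg.hot_day_effect == "flat" else None
        ),
    }
    return timeline, weather, truth


def timeline_bursts(
    timeline: pd.DataFrame,
    model: dict[str, BehaviourSignal] = DEFAULT_SIGNAL_MODELS,
    fs: float = DEFAULT_FS,
    n: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
) -> list[AccBurst]:
    """Raw (unlabelled) bursts matching a timeline's behaviour labels."""
    rng = np.random.default_rng(seed)
    out: list[AccBurst | None] = [None] * len(timeline)
    for beh in timeline["behaviour"].unique():
        idx = np.flatnonzero((timeline["behaviour"] == beh).to_numpy())
        x, y, z = _signal_matrix(beh, model, len(idx), fs, n, rng)
        for j, i in enumerate(idx):
            row = timeline.iloc[i]
            out[i] = AccBurst(
                individual_id=row["individual_id"],
                timestamp=row["timestamp"],
                fs=fs,
                x_raw=_to_counts(x[j]),
                y_raw=_to_counts(y[j]),
                z_raw=_to_counts(z[j]),
            )
    return [b for b in out if b is not None]


TRAINING_DIALECT = BurstDialect(kind="per_axis", label_col="behaviour")
SCENARIO_DIALECT = BurstDialect(kind="interleaved")


def make_fixture_suite(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write the deterministic fixture files used by tests and walkthroughs.

    Produces a labelled training set (~2000 bursts across the 12
    behaviours), a 2-individual 20-day scenario (behaviour timeline and
    raw burst file), the matching hourly weather series and the
    ground-truth record.  Regeneration with the same seed is
    byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "training": out_dir / "training_bursts.csv",
        "scenario_bursts": out_dir / "scenario_bursts.csv",
        "timeline": out_dir / "scenario_timeline.csv",
        "weather": out_dir / "weather.csv",
        "truth": out_dir / "ground_truth.json",
    }
    training = make_training_set(n_per_behaviour=170, seed=seed)
    write_bursts(training, paths["training"], TRAINING_DIALECT)

    cfg = ScenarioConfig(seed=seed)
    timeline, weather, truth = simulate_timeline(cfg)
    timeline.to_csv(paths["timeline"], index=False)
    write_weather(weather, paths["weather"])
    bursts = timeline_bursts(timeline, seed=seed + 1)
    write_bursts(bursts, paths["scenario_bursts"], SCENARIO_DIALECT)
    paths["truth"].write_text(json.dumps(truth, indent=2))
    return paths
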