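"""Seeded synthetic cohorts with known recovery dynamics.

Two generators mirror the two data streams the estimators consume.

Accelerometer metrics follow a multiplicative decay model on the log
scale with noise entering both the level and the slope:

    log y = beta_i + (a_g + b_g * eps) * z + eps,   z = 1/(t+1),  eps ~ F,

so the tau-quantile of log y is ``beta_i + F^{-1}(tau) + alpha_g(tau) z``
with a quantile-dependent true slope ``alpha_g(tau) = a_g + b_g *
F^{-1}(tau)``.  The slope noise term makes tail and central quantiles
recover at genuinely different rates, the pattern the quantile-regression
estimator is built to detect.  F defaults to the standard normal;
``|b_g| <= 1`` keeps the conditional quantile function monotone for z in
(0, 1].

Dive records are drawn hour by hour: dive counts are Poisson, categories
are i.i.d. from a depth-category mixture that relaxes from a perturbed
composition to a baseline one at a known changepoint ``t_star`` (step, or
exponential approach), and durations are lognormal with category-specific
medians.  Records are truncated at staggered drop times so the
drop-weighted reference distribution machinery is exercised.

All generators are pure functions of (scenario, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import CATEGORIES, DIVE_COLUMNS, MetricSeries

__all__ = [
    "AccelScenario",
    "DiveScenario",
    "simulate_accel",
    "simulate_dives",
    "simulate_cohort",
    "true_alpha",
    "true_recovery_time",
]


def _from_yaml(cls, path):
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    for key in ("slopes",):
        if key in raw and isinstance(raw[key], dict):
            raw[key] = {g: tuple(v) for g, v in raw[key].items()}
    for key in ("beta_range", "pi_perturbed", "pi_baseline", "duration_medians_s",
                "drop_times_h"):
        if raw.get(key) is not None:
            raw[key] = tuple(raw[key])
    return cls(**raw)


def true_alpha(a_g: float, b_g: float, tau: float) -> float:
    """Quantile-level slope implied by the generator: a + b * Phi^{-1}(tau)."""
    return a_g + b_g * stats.norm.ppf(tau)


def true_recovery_time(alpha: float, delta: float = 0.25) -> float:
    """Closed-form return time matching the estimator's definition."""
    return max(0.0, abs(alpha) / abs(np.log(delta)) - 1.0)


@dataclass
class AccelScenario:
    """Accelerometer-cohort generator settings.

    ``slopes`` maps group name -> (a_g, b_g).  Defaults give two
    handling-time groups whose median slopes differ strongly, 10 animals
    per group, 100 h records at one observation per minute.
    """

    n_animals: int = 10
    duration_h: float = 100.0
    obs_per_h: int = 60
    beta_range: tuple[float, float] = (0.5, 1.5)
    slopes: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"Long": (-2.5, -1.0), "Short": (-0.5, -1.0)}
    )
    metric_name: str = "VeDBA"
    seed: int = 0

    def __post_init__(self) -> None:
        for g, (_, b) in self.slopes.items():
            if abs(b) > 1.0:
                raise ValueError(
                    f"group {g!r}: |b| must be <= 1 to keep quantiles monotone"
                )

    @classmethod
    def from_yaml(cls, path) -> "AccelScenario":
        """Load a scenario from a YAML mapping of field names to values."""
        return _from_yaml(cls, path)

    def truth(self, taus=(0.5, 0.9), delta: float = 0.25) -> dict:
        """Ground-truth slopes and return times per group and tau."""
        out = {}
        for g, (a, b) in self.slopes.items():
            out[g] = {
                tau: {
                    "alpha": true_alpha(a, b, tau),
                    "t_r": true_recovery_time(true_alpha(a, b, tau), delta),
                }
                for tau in taus
            }
        return out


def simulate_accel(
    sc: AccelScenario,
) -> tuple[list[MetricSeries], dict[str, str], dict]:
    """Generate per-animal metric series plus the ground-truth record.

    Returns (series, group_of_animal, truth).  Observation times sit at
    bin centres ``(k + 0.5)/obs_per_h`` hours since release, matching the
    timestamps of aggregated real metrics.
    """
    rng = np.random.default_rng(sc.seed)
    n_obs = int(round(sc.duration_h * sc.obs_per_h))
    t = (np.arange(n_obs) + 0.5) / sc.obs_per_h
    z = 1.0 / (t + 1.0)
    series: list[MetricSeries] = []
    group_of: dict[str, str] = {}
    betas: dict[str, float] = {}
    for g in sorted(sc.slopes):
        a_g, b_g = sc.slopes[g]
        for i in range(sc.n_animals):
            animal = f"{g}{i + 1:02d}"
            beta = rng.uniform(*sc.beta_range)
            eps = rng.standard_normal(n_obs)
            log_y = beta + (a_g + b_g * eps) * z + eps
            series.append(
                MetricSeries(
                    t, np.exp(log_y), sc.metric_name, animal_id=animal,
                    aggregation_window_min=60.0 / sc.obs_per_h,
                )
            )
            group_of[animal] = g
            betas[animal] = beta
    truth = {"slopes": dict(sc.slopes), "beta_ind": betas, "per_group": sc.truth()}
    return series, group_of, truth


@dataclass
class DiveScenario:
    """Dive-record generator settings.

    The category mixture is ``pi_perturbed`` before ``t_star`` and
    ``pi_baseline`` after (``transition='step'``), or relaxes as
    ``pi_base + (pi0 - pi_base) * exp(-t / kappa)`` (``'exponential'``).
    Durations are lognormal with category medians of 120/420/720 s — the
    synthetic defaults mimic progressively longer deep dives and are not
    field measurements.  ``drop_times_h=None`` staggers record ends
    between 70% and 100% of ``duration_h``.
    """

    n_animals: int = 10
    duration_h: float = 100.0
    dives_per_h: float = 6.0
    pi_perturbed: tuple[float, float, float] = (0.9, 0.08, 0.02)
    pi_baseline: tuple[float, float, float] = (0.5, 0.3, 0.2)
    t_star: float = 12.0
    transition: str = "step"
    kappa: float = 6.0
    duration_medians_s: tuple[float, float, float] = (120.0, 420.0, 720.0)
    duration_sigma: float = 0.5
    drop_times_h: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pi_perturbed", "pi_baseline"):
            pi = np.asarray(getattr(self, name), dtype=float)
            if np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be a probability vector")
        if self.transition not in ("step", "exponential"):
            raise ValueError("transition must be 'step' or 'exponential'")
        if self.drop_times_h is not None and len(self.drop_times_h) != self.n_animals:
            raise ValueError("need one drop time per animal")

    @classmethod
    def from_yaml(cls, path) -> "DiveScenario":
        """Load a scenario from a YAML mapping of field names to values."""
        return _from_yaml(cls, path)

    def resolved_drop_times(self) -> np.ndarray:
        if self.drop_times_h is not None:
            return np.asarray(self.drop_times_h, dtype=float)
        if self.n_animals == 1:
            return np.array([self.duration_h])
        return np.round(np.linspace(0.7, 1.0, self.n_animals) * self.duration_h)

    def pi_at(self, t: float) -> np.ndarray:
        p0 = np.asarray(self.pi_perturbed)
        pb = np.asarray(self.pi_baseline)
        if self.transition == "step":
            return p0 if t < self.t_star else pb
        return pb + (p0 - pb) * np.exp(-t / self.kappa)


def simulate_dives(sc: DiveScenario) -> tuple[pd.DataFrame, dict]:
    """Generate a pooled dive table plus the ground-truth record.

    Hourly dive counts are Poisson(``dives_per_h``) per animal, start
    times uniform within the hour, categories i.i.d. from the mixture at
    the start time, durations lognormal per category.  Each animal's
    record is truncated at its drop time.
    """
    rng = np.random.default_rng(sc.seed)
    drops = sc.resolved_drop_times()
    medians = np.asarray(sc.duration_medians_s, dtype=float)
    rows: list[tuple] = []
    for i in range(sc.n_animals):
        animal = f"A{i + 1:02d}"
        end = drops[i]
        for hour in range(int(np.ceil(end))):
            count = rng.poisson(sc.dives_per_h)
            if count == 0:
                continue
            starts = hour + np.sort(rng.uniform(size=count))
            starts = starts[starts < end]
            for s in starts:
                cat_idx = rng.choice(3, p=sc.pi_at(s))
                dur = float(
                    np.exp(np.log(medians[cat_idx]) + sc.duration_sigma * rng.standard_normal())
                )
                rows.append((animal, float(s), dur, float("nan"), CATEGORIES[cat_idx]))
    table = pd.DataFrame(rows, columns=DIVE_COLUMNS)
    truth = {
        "t_star": sc.t_star,
        "pi_perturbed": tuple(sc.pi_perturbed),
        "pi_baseline": tuple(sc.pi_baseline),
        "drop_times_h": drops.tolist(),
    }
    return table, truth


def simulate_cohort(
    accel_sc: AccelScenario,
    dive_sc: DiveScenario,
    out_dir: str | Path,
    species: str = "narwhal",
) -> dict:
    """Write a full synthetic input bundle in the pipeline's CSV dialects.

    Produces ``metadata.csv``, ``dives.csv`` and one
    ``metrics/<animal>_<metric>.csv`` per animal, with dive-table animal
    ids remapped onto the accelerometer cohort so both streams describe
    the same animals.  Handling times are drawn consistently with the
    accelerometer group labels (short < 58 min <= long).  Returns a
    manifest of written paths and the ground-truth records.
    """
    if dive_sc.n_animals != accel_sc.n_animals * len(accel_sc.slopes):
        raise ValueError(
            "dive scenario must cover the same number of animals as the "
            "accelerometer scenario (n_animals * number of groups)"
        )
    out_dir = Path(out_dir)
    (out_dir / "metrics").mkdir(parents=True, exist_ok=True)
    series, group_of, accel_truth = simulate_accel(accel_sc)
    dives, dive_truth = simulate_dives(dive_sc)

    animals = sorted(group_of)
    dive_ids = sorted(dives["animal_id"].unique())
    rename = dict(zip(dive_ids, animals))
    dives = dives.assign(animal_id=dives["animal_id"].map(rename))
    dive_path = out_dir / "dives.csv"
    dives.to_csv(dive_path, index=False)

    drops = dict(zip([rename[d] for d in dive_ids], dive_sc.resolved_drop_times()))
    rng = np.random.default_rng(np.random.SeedSequence([accel_sc.seed, 977]))
    meta_rows = []
    for a in animals:
        g = group_of[a]
        handling = (
            int(rng.integers(58, 91)) if g.lower().startswith("long")
            else int(rng.integers(18, 58))
        )
        meta_rows.append(
            {
                "animal_id": a,
                "species": species,
                "sex": str(rng.choice(["F", "M"])),
                "handling_time_min": handling,
                "group": g,
                "record_h": float(drops[a]),
            }
        )
    metadata = pd.DataFrame(meta_rows)
    meta_path = out_dir / "metadata.csv"
    metadata.to_csv(meta_path, index=False)

    metric_paths = []
    for m in series:
        p = out_dir / "metrics" / f"{m.animal_id}_{m.metric_name}.csv"
        pd.DataFrame({"time_h": m.time_h, "value": m.value}).to_csv(p, index=False)
        metric_paths.append(str(p))

    return {
        "metadata": str(meta_path),
        "dives": str(dive_path),
        "metrics": metric_paths,
        "truth": {
            "accel": accel_truth,
            "dives": dive_truth,
        },
        "scenarios": {
            "accel": dataclasses.asdict(accel_sc),
            "dives": dataclasses.asdict(dive_sc),
        },
    }
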