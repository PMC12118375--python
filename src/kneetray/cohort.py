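"""Patient cohorts for primary total knee arthroplasty.

A cohort is a plain :class:`pandas.DataFrame` with one row per TKA case and
columns ``sex, height_cm, weight_kg, bmi, side, femur_size, femur_type,
insert_thickness_mm, patellar_resurfacing``. The raw registry extract behind
the reference summary is not redistributable, so this module provides

* :func:`reference_summary` — the packaged frequency/mean summary of the
  4,980-case registry cohort (the quantity all tray accounting needs);
* :func:`generate_cohort` — a seeded synthetic cohort whose marginal
  distributions match that summary and whose femoral sizes are drawn from
  the registry-fitted multinomial logit (see :mod:`kneetray.size_model`),
  with intercepts calibrated so the simulated size marginals match the
  observed ones;
* CSV round-trip I/O with registry-style cleaning: complete cases only,
  with implausible anthropometrics rejected and counted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import numpy as np
import pandas as pd

from .size_model import (MODEL_SIZES, PREDICTORS, normalize_size,
                         reference_log_odds)

SIZE_LEVELS = ("1.5", "2", "2.5", "3", "4N", "4", "5", "6")
INSERT_LEVELS = ("8", "10", "12.5", "15", "17.5", "20", "22.5")
COLUMNS = ("sex", "height_cm", "weight_kg", "bmi", "side", "femur_size",
           "femur_type", "insert_thickness_mm", "patellar_resurfacing")

# plausibility gates for registry-style cleaning
HEIGHT_RANGE = (100.0, 230.0)
WEIGHT_RANGE = (30.0, 250.0)
BMI_RANGE = (12.0, 70.0)
#: tolerated gap between reported BMI and weight/height²-derived BMI
BMI_TOLERANCE = 0.5

_CONTINUOUS = ("height_cm", "weight_kg", "bmi")
_CATEGORY_LEVELS = {
    "sex": ("male", "female"),
    "side": ("left", "right"),
    "femur_type": ("CR", "PS"),
}


# ------------------------------------------------------------------ summary

@dataclass(frozen=True)
class CohortSummary:
    """Counts per category level plus mean/SD of the anthropometrics."""

    n_total: int
    counts: dict
    continuous: dict

    def __post_init__(self):
        for var, levels in self.counts.items():
            if var == "tibia_size":   # carried as metadata only
                continue
            total = sum(levels.values())
            if total != self.n_total:
                raise ValueError(
                    f"counts for {var!r} sum to {total}, expected {self.n_total}")

    def proportions(self, variable: str) -> dict:
        levels = self.counts[variable]
        return {k: v / self.n_total for k, v in levels.items()}

    def count(self, variable: str, level) -> int:
        return int(self.counts[variable][str(level).lower()
                                         if isinstance(level, bool) else str(level)])


def reference_summary() -> CohortSummary:
    """Packaged summary of the registry cohort (N = 4,980)."""
    text = resources.files("kneetray").joinpath("data/reference_cohort.json").read_text()
    doc = json.loads(text)
    continuous = {k: (v["mean"], v["sd"]) for k, v in doc["continuous"].items()}
    counts = {var: {k: int(n) for k, n in levels.items()}
              for var, levels in doc["counts"].items()}
    return CohortSummary(n_total=int(doc["n_total"]), counts=counts, continuous=continuous)


def summarize_cohort(cohort: pd.DataFrame) -> CohortSummary:
    """Frequency/mean summary of a cohort table."""
    counts = {}
    for var in ("sex", "side", "femur_type", "femur_size",
                "insert_thickness_mm", "patellar_resurfacing"):
        vc = cohort[var].value_counts()
        if var == "patellar_resurfacing":
            counts[var] = {"true": int(vc.get(True, 0)), "false": int(vc.get(False, 0))}
        else:
            counts[var] = {str(k): int(v) for k, v in vc.items()}
    continuous = {v: (float(cohort[v].mean()), float(cohort[v].std(ddof=1)))
                  if len(cohort) else (np.nan, np.nan) for v in _CONTINUOUS}
    return CohortSummary(n_total=len(cohort), counts=counts, continuous=continuous)


# ---------------------------------------------------------------- generator

def _default_insert_probs() -> dict:
    ref = reference_summary()
    return ref.proportions("insert_thickness_mm")


def _default_size_targets() -> dict:
    """Marginal targets for the 7 modeled sizes ("4N" merged into "4")."""
    ref = reference_summary()
    raw = dict(ref.counts["femur_size"])
    raw["4"] = raw["4"] + raw.pop("4N")
    return {s: raw[s] / ref.n_total for s in MODEL_SIZES}


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic-cohort generating process.

    The defaults reproduce the reference cohort: marginal category
    frequencies and pooled anthropometric moments are taken from its
    summary, and femoral size is generated from the registry-fitted
    multinomial logit (``slopes`` = log odds ratios) with intercepts
    calibrated so the model-implied size marginals match ``size_targets``.

    Sex-conditional height means are placed ``sex_height_gap_cm`` apart
    (default 15 cm, a typical adult sexual dimorphism) around the pooled
    mean, and the within-sex SD is solved so the pooled SD is matched
    exactly. Weight is linear in height (``weight_height_slope`` kg/cm,
    default 0.8) plus a Gaussian residual solved the same way; BMI is
    computed from height and weight, never drawn.
    """

    n: int
    seed: int = 0
    female_frac: float = 3154 / 4980
    right_frac: float = 2614 / 4980
    ps_frac: float = 3411 / 4980
    resurfacing_frac: float = 3902 / 4980
    insert_probs: dict = field(default_factory=_default_insert_probs)
    height_mean: float = 168.6
    height_sd: float = 9.7
    sex_height_gap_cm: float = 15.0
    weight_mean: float = 85.3
    weight_sd: float = 15.6
    weight_height_slope: float = 0.8
    size_targets: dict = field(default_factory=_default_size_targets)
    narrow_frac: float = 346 / 1476     # share of size-4 draws that are 4 Narrow
    slopes: pd.DataFrame = field(default_factory=reference_log_odds)
    calibration_n: int = 200_000
    calibration_seed: int = 777_001
    calibration_tol: float = 1e-3
    calibration_max_iter: int = 500

    def validate(self):
        if self.n < 0:
            raise ValueError("n must be non-negative")
        for name in ("female_frac", "right_frac", "ps_frac", "resurfacing_frac",
                     "narrow_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name, probs in (("insert_probs", self.insert_probs),
                            ("size_targets", self.size_targets)):
            vals = np.asarray(list(probs.values()), dtype=float)
            if np.any(vals < 0) or np.any(vals > 1) or abs(vals.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be proportions summing to 1")
        pf = self.female_frac
        if self.height_sd ** 2 <= pf * (1 - pf) * self.sex_height_gap_cm ** 2:
            raise ValueError("pooled height SD too small for the sex height gap")
        if self.weight_sd ** 2 <= (self.weight_height_slope * self.height_sd) ** 2:
            raise ValueError("pooled weight SD too small for the height slope")


def _sex_height_params(cfg: GeneratorConfig):
    pf = cfg.female_frac
    mu_f = cfg.height_mean - (1 - pf) * cfg.sex_height_gap_cm
    mu_m = mu_f + cfg.sex_height_gap_cm
    within_sd = np.sqrt(cfg.height_sd ** 2 - pf * (1 - pf) * cfg.sex_height_gap_cm ** 2)
    resid_sd = np.sqrt(cfg.weight_sd ** 2 - (cfg.weight_height_slope * cfg.height_sd) ** 2)
    return mu_f, mu_m, within_sd, resid_sd


def _sample_predictors(rng: np.random.Generator, cfg: GeneratorConfig, n: int) -> pd.DataFrame:
    """Draw the five predictors; anthropometrics are redrawn until plausible."""
    mu_f, mu_m, within_sd, resid_sd = _sex_height_params(cfg)
    female = rng.random(n) < cfg.female_frac
    mu = np.where(female, mu_f, mu_m)
    height = rng.normal(mu, within_sd)
    weight = (cfg.weight_mean + cfg.weight_height_slope * (height - cfg.height_mean)
              + rng.normal(0.0, resid_sd, n))
    for _ in range(100):
        bmi = weight / (height / 100.0) ** 2
        bad = ~((height >= HEIGHT_RANGE[0]) & (height <= HEIGHT_RANGE[1])
                & (weight >= WEIGHT_RANGE[0]) & (weight <= WEIGHT_RANGE[1])
                & (bmi >= BMI_RANGE[0]) & (bmi <= BMI_RANGE[1]))
        if not bad.any():
            break
        nb = int(bad.sum())
        height[bad] = rng.normal(mu[bad], within_sd)
        weight[bad] = (cfg.weight_mean
                       + cfg.weight_height_slope * (height[bad] - cfg.height_mean)
                       + rng.normal(0.0, resid_sd, nb))
    right = rng.random(n) < cfg.right_frac
    return pd.DataFrame({
        "sex_female": female.astype(float),
        "height_cm": height,
        "weight_kg": weight,
        "bmi": weight / (height / 100.0) ** 2,
        "side_right": right.astype(float),
    })


_CALIBRATION_CACHE: dict = {}


def _calibration_key(cfg: GeneratorConfig):
    return (cfg.female_frac, cfg.right_frac, cfg.height_mean, cfg.height_sd,
            cfg.sex_height_gap_cm, cfg.weight_mean, cfg.weight_sd,
            cfg.weight_height_slope,
            tuple(sorted(cfg.size_targets.items())),
            cfg.slopes.to_numpy().tobytes(),
            cfg.calibration_n, cfg.calibration_seed, cfg.calibration_tol)


def calibrate_intercepts(cfg: GeneratorConfig) -> pd.Series:
    """Solve the generating intercepts by fixed-point iteration.

    The published model reports only odds ratios, so the intercepts of the
    size-generating multinomial logit are free. They are chosen so that the
    model-implied marginal size distribution — averaged over a large Monte
    Carlo draw of the predictor distribution — matches ``size_targets``:
    iterate ``alpha_k += log(target_k / implied_k)`` (anchoring size 3 at 0)
    until the largest log discrepancy falls below ``calibration_tol``.
    """
    key = _calibration_key(cfg)
    if key in _CALIBRATION_CACHE:
        return _CALIBRATION_CACHE[key].copy()
    rng = np.random.default_rng(cfg.calibration_seed)
    X = _sample_predictors(rng, cfg, cfg.calibration_n)[list(PREDICTORS)].to_numpy()
    B = cfg.slopes.loc[list(MODEL_SIZES), list(PREDICTORS)].to_numpy()
    eta0 = X @ B.T
    targets = np.asarray([cfg.size_targets[s] for s in MODEL_SIZES])
    ref_idx = MODEL_SIZES.index("3")
    alpha = np.log(targets)
    alpha -= alpha[ref_idx]
    for _ in range(cfg.calibration_max_iter):
        z = alpha + eta0
        z -= z.max(axis=1, keepdims=True)
        p = np.exp(z)
        p /= p.sum(axis=1, keepdims=True)
        implied = p.mean(axis=0)
        delta = np.log(targets) - np.log(implied)
        if np.max(np.abs(delta)) < cfg.calibration_tol:
            break
        alpha += delta
        alpha -= alpha[ref_idx]
    else:
        raise RuntimeError("intercept calibration did not converge")
    out = pd.Series(alpha, index=list(MODEL_SIZES))
    _CALIBRATION_CACHE[key] = out.copy()
    return out


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Seeded synthetic cohort; byte-identical for identical config."""
    config.validate()
    alpha = calibrate_intercepts(config)
    rng = np.random.default_rng(config.seed)
    n = config.n
    pred = _sample_predictors(rng, config, n)

    B = config.slopes.loc[list(MODEL_SIZES), list(PREDICTORS)].to_numpy()
    z = alpha.to_numpy() + pred[list(PREDICTORS)].to_numpy() @ B.T
    z -= z.max(axis=1, keepdims=True)
    p = np.exp(z)
    p /= p.sum(axis=1, keepdims=True)
    u = rng.random(n)
    size_idx = (u[:, None] > np.cumsum(p, axis=1)).sum(axis=1)
    sizes = np.asarray(MODEL_SIZES, dtype=object)[size_idx]
    is4 = sizes == "4"
    narrow = rng.random(int(is4.sum())) < config.narrow_frac
    sizes[np.nonzero(is4)[0][narrow]] = "4N"

    femur_type = np.where(rng.random(n) < config.ps_frac, "PS", "CR")
    insert_levels = list(config.insert_probs)
    insert_p = np.asarray([config.insert_probs[k] for k in insert_levels])
    insert = rng.choice(np.asarray(insert_levels, dtype=object), size=n, p=insert_p)
    resurfacing = rng.random(n) < config.resurfacing_frac

    return pd.DataFrame({
        "sex": np.where(pred["sex_female"].to_numpy() > 0.5, "female", "male"),
        "height_cm": pred["height_cm"].to_numpy(),
        "weight_kg": pred["weight_kg"].to_numpy(),
        "bmi": pred["bmi"].to_numpy(),
        "side": np.where(pred["side_right"].to_numpy() > 0.5, "right", "left"),
        "femur_size": sizes.astype(str),
        "femur_type": femur_type.astype(str),
        "insert_thickness_mm": insert.astype(str),
        "patellar_resurfacing": resurfacing,
    }, columns=list(COLUMNS))


def design_matrix(cohort: pd.DataFrame) -> pd.DataFrame:
    """Predictor matrix (columns :data:`~kneetray.size_model.PREDICTORS`)."""
    return pd.DataFrame({
        "sex_female": (cohort["sex"] == "female").astype(float),
        "height_cm": cohort["height_cm"].astype(float),
        "weight_kg": cohort["weight_kg"].astype(float),
        "bmi": cohort["bmi"].astype(float),
        "side_right": (cohort["side"] == "right").astype(float),
    })


# ----------------------------------------------------------------- CSV I/O

@dataclass(frozen=True)
class ExclusionReport:
    """Rows dropped on read, mirroring complete-case registry cleaning."""

    n_rows: int
    missing_rows: tuple
    implausible_rows: tuple

    @property
    def n_missing(self) -> int:
        return len(self.missing_rows)

    @property
    def n_implausible(self) -> int:
        return len(self.implausible_rows)

    @property
    def n_excluded(self) -> int:
        return self.n_missing + self.n_implausible

    @property
    def n_kept(self) -> int:
        return self.n_rows - self.n_excluded


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort.loc[:, list(COLUMNS)].to_csv(path, index=False)


def _normalize_insert(value, row: int) -> str:
    s = str(value).strip()
    try:
        f = float(s)
    except ValueError:
        raise ValueError(f"row {row}: unparseable insert_thickness_mm {value!r}")
    for level in INSERT_LEVELS:
        if f == float(level):
            return level
    raise ValueError(f"row {row}: unknown insert_thickness_mm {value!r}")


_BOOL_MAP = {"true": True, "false": False, "1": True, "0": False,
             "yes": True, "no": False}


def read_cohort_csv(path) -> tuple[pd.DataFrame, ExclusionReport]:
    """Read a cohort CSV with complete-case filtering.

    Rows with any missing field are excluded and counted; rows failing the
    plausibility gates (height 100–230 cm, weight 30–250 kg, BMI 12–70,
    reported BMI within 0.5 of weight/height²) are excluded and counted
    separately. A value that is present but not a recognized category level
    raises ``ValueError`` naming the offending data row (1-based).
    """
    raw = pd.read_csv(path, dtype=str)
    missing_cols = [c for c in COLUMNS if c not in raw.columns]
    if missing_cols:
        raise ValueError(f"cohort CSV is missing columns {missing_cols}")
    raw = raw.loc[:, list(COLUMNS)]
    stripped = raw.apply(lambda s: s.str.strip())
    missing_mask = stripped.isna().any(axis=1) | (stripped == "").any(axis=1)

    records, implausible = [], []
    for i in stripped.index[~missing_mask]:
        row = i + 1  # 1-based data row (header excluded)
        r = stripped.loc[i]
        rec = {}
        for col, levels in _CATEGORY_LEVELS.items():
            val = r[col] if col == "femur_type" else r[col].lower()
            if val not in levels:
                raise ValueError(f"row {row}: unknown {col} level {r[col]!r}")
            rec[col] = val
        try:
            rec["femur_size"] = normalize_size(r["femur_size"])
        except ValueError as exc:
            raise ValueError(f"row {row}: {exc}")
        rec["insert_thickness_mm"] = _normalize_insert(r["insert_thickness_mm"], row)
        b = r["patellar_resurfacing"].lower()
        if b not in _BOOL_MAP:
            raise ValueError(f"row {row}: unparseable patellar_resurfacing {r['patellar_resurfacing']!r}")
        rec["patellar_resurfacing"] = _BOOL_MAP[b]
        for col in _CONTINUOUS:
            try:
                rec[col] = float(r[col])
            except ValueError:
                raise ValueError(f"row {row}: unparseable {col} value {r[col]!r}")
        derived_bmi = rec["weight_kg"] / (rec["height_cm"] / 100.0) ** 2
        ok = (HEIGHT_RANGE[0] <= rec["height_cm"] <= HEIGHT_RANGE[1]
              and WEIGHT_RANGE[0] <= rec["weight_kg"] <= WEIGHT_RANGE[1]
              and BMI_RANGE[0] <= rec["bmi"] <= BMI_RANGE[1]
              and abs(rec["bmi"] - derived_bmi) <= BMI_TOLERANCE)
        if not ok:
            implausible.append(row)
            continue
        records.append(rec)

    report = ExclusionReport(
        n_rows=len(raw),
        missing_rows=tuple(int(i) + 1 for i in stripped.index[missing_mask]),
        implausible_rows=tuple(implausible),
    )
    if records:
        df = pd.DataFrame.from_records(records, columns=list(COLUMNS))
    else:
        df = pd.DataFrame({c: pd.Series(dtype=object) for c in COLUMNS})
        for c in _CONTINUOUS:
            df[c] = df[c].astype(float)
        df["patellar_resurfacing"] = df["patellar_resurfacing"].astype(bool)
    df = df.reset_index(drop=True)
    return df, report
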