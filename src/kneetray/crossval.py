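"""Repeated hold-out evaluation of tray scenarios.

Each replication randomly splits the cohort 80/20, fits the size model on
the training part, and scores every scenario on the same test part, so that
scenario comparisons are paired (one model fit serves all scenarios of a
replication). Accuracy is averaged across replications and its interval is
the 2.5–97.5 percentile range of the replication accuracies; tray demand is
reported as size-specific surgical trays per 100 treated patients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import design_matrix
from .size_model import MODEL_SIZES, FemoralSizeClassifier, merge_narrow
from .tray_scenarios import TrayScenario, catalog, membership_arrays

_ORDER = {s: i for i, s in enumerate(MODEL_SIZES)}


@dataclass(frozen=True)
class CVConfig:
    """Repeated hold-out settings: 500 × 80/20 by default."""

    replications: int = 500
    train_fraction: float = 0.8
    seed: int = 0
    redraw_cap: int = 20

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.replications < 1:
            raise ValueError("replications must be >= 1")


@dataclass(frozen=True)
class ScenarioEvaluation:
    """Cross-validated accuracy (with percentile interval) and tray demand."""

    scenario_id: str
    accuracy_pct: float
    accuracy_lo: float
    accuracy_hi: float
    trays_per_100: float
    n_replications: int


def _score_scenario(proba, model_to_full, actual_idx, mats, rule):
    """Per-patient set assignment, correctness and tray count (vectorized)."""
    membership, trays, cheapest = mats
    m_model = membership[:, model_to_full]               # (n_sets, K_model)
    sums = proba @ m_model.T                             # (n, n_sets)
    if rule == "sum":
        assigned = np.argmax(sums, axis=1)
    else:
        pred_full = model_to_full[np.argmax(proba, axis=1)]
        containing = membership[:, pred_full].T          # (n, n_sets)
        masked = np.where(containing, sums, -np.inf)
        assigned = np.argmax(masked, axis=1)             # first max = lower index
    correct = membership[assigned, actual_idx]
    counts = trays[assigned] + np.where(correct, 0, cheapest[actual_idx])
    return assigned, correct, counts


def evaluate_all(cohort: pd.DataFrame, cv: CVConfig | None = None,
                 scenarios: dict | None = None, rule: str = "anchored",
                 model_params: dict | None = None,
                 return_replications: bool = False):
    """Repeated hold-out metrics for every scenario (paired across splits).

    Returns a DataFrame with one row per scenario; with
    ``return_replications=True`` also the per-replication accuracy and
    tray-count matrices (replications × scenarios), for paired contrasts.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    cv = cv or CVConfig()
    scenarios = scenarios if scenarios is not None else catalog()
    ids = list(scenarios)
    mats = {sid: membership_arrays(scenarios[sid]) for sid in ids}

    X = design_matrix(cohort).to_numpy()
    y = merge_narrow(cohort["femur_size"].to_numpy())
    actual_idx_all = np.asarray([_ORDER[s] for s in y])
    n = len(y)
    n_train = int(round(cv.train_fraction * n))
    if not 0 < n_train < n:
        raise ValueError("cohort too small for the requested train fraction")

    rng = np.random.default_rng(cv.seed)
    acc = np.empty((cv.replications, len(ids)))
    trays = np.empty((cv.replications, len(ids)))
    n_redraws = 0
    for r in range(cv.replications):
        for _ in range(cv.redraw_cap):
            perm = rng.permutation(n)
            train, test = perm[:n_train], perm[n_train:]
            if len(np.unique(y[train])) >= 2:
                break
            n_redraws += 1
        else:
            raise RuntimeError(
                f"could not draw a training split with >=2 size classes "
                f"in {cv.redraw_cap} attempts")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # rare-class convergence chatter
            model = FemoralSizeClassifier(**(model_params or {})).fit(X[train], y[train])
        proba = model.predict_proba(X[test])
        model_to_full = np.asarray([_ORDER[c] for c in model.classes_])
        actual_idx = actual_idx_all[test]
        for j, sid in enumerate(ids):
            _, correct, counts = _score_scenario(proba, model_to_full,
                                                 actual_idx, mats[sid], rule)
            acc[r, j] = 100.0 * correct.mean()
            trays[r, j] = counts.mean()
    if n_redraws:
        warnings.warn(f"{n_redraws} training split(s) redrawn for lacking "
                      "2 size classes", stacklevel=2)

    rows = []
    for j, sid in enumerate(ids):
        sc: TrayScenario = scenarios[sid]
        rows.append({
            "scenario_id": sid,
            "sets": sc.describe(),
            "overlap": sc.overlap,
            "accuracy_pct": acc[:, j].mean(),
            "accuracy_lo": np.percentile(acc[:, j], 2.5),
            "accuracy_hi": np.percentile(acc[:, j], 97.5),
            "trays_per_100": 100.0 * trays[:, j].mean(),
        })
    table = pd.DataFrame(rows)
    if return_replications:
        return table, acc, trays
    return table


def repeated_holdout(cohort: pd.DataFrame, scenario: TrayScenario,
                     cv: CVConfig | None = None, **kwargs) -> ScenarioEvaluation:
    """Evaluate a single scenario; see :func:`evaluate_all`."""
    cv = cv or CVConfig()
    table = evaluate_all(cohort, cv, scenarios={scenario.id: scenario}, **kwargs)
    row = table.iloc[0]
    return ScenarioEvaluation(
        scenario_id=scenario.id,
        accuracy_pct=float(row["accuracy_pct"]),
        accuracy_lo=float(row["accuracy_lo"]),
        accuracy_hi=float(row["accuracy_hi"]),
        trays_per_100=float(row["trays_per_100"]),
        n_replications=cv.replications,
    )
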