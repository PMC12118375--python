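"""Surgical-tray usage accounting in DIN units.

DIN is the standardized surgical tray footprint (1 DIN = 480 × 250 mm;
trays also come in 0.5 DIN). A tray *setup rule* charges a base DIN per
case plus conditional add-ons: outlier femoral sizes housed on separate
trays, the posterior-stabilized (PS) box-guide tray under the standard
setup, and — under the optimized setup built around a two-range tray with
an overlapping size — the relocated 15 mm trial-insert and patellar
resurfacing trays plus one extra tray whenever the preoperative size
prediction misses the prepared range.

All DIN amounts are multiples of 0.5 and are accumulated in exact half-DIN
integer arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .cohort import CohortSummary

_HALF = 2  # internal unit: half-DIN


def _to_halves(din: float, what: str) -> int:
    h = din * _HALF
    if abs(h - round(h)) > 1e-9 or din < 0:
        raise ValueError(f"{what} must be a non-negative multiple of 0.5 DIN, got {din}")
    return int(round(h))


@dataclass(frozen=True)
class AddOn:
    """One conditional tray charge.

    Either ``variable``/``level`` select a cohort-count predicate (e.g.
    femur_size == "6"), or ``rate`` charges a per-case probability (the
    triggered cases are ``round(rate × n)`` — trays are opened for whole
    cases).
    """

    label: str
    din_per_case: float
    variable: str | None = None
    level: str | None = None
    rate: float | None = None

    def __post_init__(self):
        _to_halves(self.din_per_case, f"add-on {self.label!r}")
        if (self.variable is None) == (self.rate is None):
            raise ValueError("an add-on needs exactly one of variable/level or rate")
        if self.rate is not None and not 0.0 <= self.rate <= 1.0:
            raise ValueError(f"rate must be in [0, 1], got {self.rate}")


@dataclass(frozen=True)
class TraySetupRule:
    name: str
    base_label: str
    base_din_per_case: float
    addons: tuple

    def __post_init__(self):
        _to_halves(self.base_din_per_case, "base DIN")


def standard_setup() -> TraySetupRule:
    """The 7-tray standard setup: 7 DIN/case, plus outlier-size and PS trays."""
    return TraySetupRule(
        name="standard",
        base_label="Standard TKA",
        base_din_per_case=7.0,
        addons=(
            AddOn("Size 1.5", 1.0, "femur_size", "1.5"),
            AddOn("Size 4 Narrow", 0.5, "femur_size", "4N"),
            AddOn("Size 6", 1.0, "femur_size", "6"),
            AddOn("Posterior stabilized femur type", 1.0, "femur_type", "PS"),
        ),
    )


def optimized_setup(misclassification_rate: float) -> TraySetupRule:
    """The 6-tray optimized setup.

    PS instruments fit the reorganized range tray (no PS add-on); the 15 mm
    trial inserts move to a 0.5 DIN on-demand tray and patellar resurfacing
    to a 1 DIN tray; a wrong size-range prediction opens 1 extra DIN.
    """
    if not 0.0 <= misclassification_rate <= 1.0:
        raise ValueError("misclassification_rate must be in [0, 1]")
    return TraySetupRule(
        name="optimized",
        base_label="Standard TKA",
        base_din_per_case=6.0,
        addons=(
            AddOn("Size 1.5", 1.0, "femur_size", "1.5"),
            AddOn("Size 4 Narrow", 0.5, "femur_size", "4N"),
            AddOn("Size 6", 1.0, "femur_size", "6"),
            AddOn("15 mm insert", 0.5, "insert_thickness_mm", "15"),
            AddOn("Wrong predicted size", 1.0, rate=misclassification_rate),
            AddOn("Patellar resurfacing", 1.0, "patellar_resurfacing", "true"),
        ),
    )


@dataclass(frozen=True)
class DINBreakdown:
    """Line-itemized DIN totals for a cohort under one setup rule."""

    setup: str
    items: Mapping  # label -> DIN
    n_total: int

    @property
    def total(self) -> float:
        return float(sum(self.items.values()))

    def as_series(self):
        import pandas as pd
        s = pd.Series(dict(self.items), name=self.setup)
        s["Total"] = self.total
        return s


def compute_breakdown(summary: CohortSummary, rule: TraySetupRule) -> DINBreakdown:
    """Apply a setup rule to cohort counts; exact to 0.5 DIN."""
    halves = {rule.base_label: summary.n_total * _to_halves(rule.base_din_per_case, "base")}
    for addon in rule.addons:
        if addon.rate is not None:
            cases = round(addon.rate * summary.n_total)
        else:
            var_counts = summary.counts.get(addon.variable)
            if var_counts is None:
                raise ValueError(f"cohort summary lacks counts for {addon.variable!r}")
            if addon.level not in var_counts:
                cases = 0
            else:
                cases = int(var_counts[addon.level])
        halves[addon.label] = halves.get(addon.label, 0) + cases * _to_halves(
            addon.din_per_case, addon.label)
    items = {label: h / _HALF for label, h in halves.items()}
    return DINBreakdown(setup=rule.name, items=items, n_total=summary.n_total)


def case_din(rule: TraySetupRule, case: Mapping) -> float:
    """DIN charged for a single case (rate-based add-ons do not apply)."""
    total = _to_halves(rule.base_din_per_case, "base")
    for addon in rule.addons:
        if addon.rate is not None:
            continue
        value = case.get(addon.variable)
        if isinstance(value, bool):
            value = "true" if value else "false"
        if value is not None and str(value) == addon.level:
            total += _to_halves(addon.din_per_case, addon.label)
    return total / _HALF


def reduction_pct(standard: DINBreakdown, optimized: DINBreakdown) -> float:
    """Percentage DIN saved by the optimized setup, to one decimal.

    Negative when the optimized setup needs more (sign is preserved).
    """
    if standard.total <= 0:
        raise ValueError("standard total must be positive")
    return round(100.0 * (standard.total - optimized.total) / standard.total, 1)


def din_report(summary: CohortSummary, accuracy_pct: float,
               accuracy_interval: tuple | None = None) -> dict:
    """Standard-vs-optimized breakdowns from a cross-validated accuracy.

    The misclassification rate is ``1 - accuracy/100``; when an accuracy
    interval ``(lo, hi)`` is given the optimized total and the reduction
    carry intervals (lower accuracy bound -> upper tray bound).
    """
    std = compute_breakdown(summary, standard_setup())
    opt = compute_breakdown(summary, optimized_setup(1.0 - accuracy_pct / 100.0))
    out = {"standard": std, "optimized": opt, "reduction_pct": reduction_pct(std, opt)}
    if accuracy_interval is not None:
        lo, hi = accuracy_interval
        opt_hi = compute_breakdown(summary, optimized_setup(1.0 - lo / 100.0))
        opt_lo = compute_breakdown(summary, optimized_setup(1.0 - hi / 100.0))
        out["optimized_total_interval"] = (opt_lo.total, opt_hi.total)
        out["reduction_pct_interval"] = (reduction_pct(std, opt_hi),
                                         reduction_pct(std, opt_lo))
    return out
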