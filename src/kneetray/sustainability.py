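"""Carbon and cost consequences of tray reduction.

Carbon scales with tray footprint (kgCO₂eq per DIN, from a Dutch-hospital
life-cycle figure), discounted by the emission reduction that reusable
rigid sterilization containers already achieve over single-use wrap; cost
scales with tray count (a size-agnostic UK per-tray decontamination cost).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class SustainabilityParams:
    """Hospital-specific conversion factors (defaults: published estimates)."""

    carbon_per_din: float = 2.14            # kgCO2eq per 1 DIN tray sterilized
    reusable_container_reduction: float = 0.52   # GHG cut from rigid containers
    cost_per_tray_eur: float = 29.6         # decontamination cost per tray

    def __post_init__(self):
        if not 0.0 <= self.reusable_container_reduction <= 1.0:
            raise ValueError("reusable_container_reduction must be in [0, 1]")
        if self.carbon_per_din < 0 or self.cost_per_tray_eur < 0:
            raise ValueError("carbon and cost factors must be non-negative")


def carbon_per_reduced_tray(params: SustainabilityParams | None = None) -> float:
    """kgCO₂eq saved per 1 DIN of tray eliminated, to two decimals."""
    p = params or SustainabilityParams()
    return round(p.carbon_per_din * (1.0 - p.reusable_container_reduction), 2)


def totals(din_saved: float, trays_saved: float,
           params: SustainabilityParams | None = None) -> tuple:
    """(kgCO₂eq saved, EUR saved); carbon per DIN saved, cost per tray saved.

    Internal arithmetic is unrounded; round for display (2 decimals carbon,
    1 decimal EUR).
    """
    if din_saved < 0 or trays_saved < 0:
        raise ValueError("savings must be non-negative")
    p = params or SustainabilityParams()
    carbon = din_saved * p.carbon_per_din * (1.0 - p.reusable_container_reduction)
    cost = trays_saved * p.cost_per_tray_eur
    return carbon, cost
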