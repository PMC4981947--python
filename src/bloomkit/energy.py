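"""Lake energy-export arithmetic for flamingo grazing.

When lesser flamingos dominate herbivory they ingest a large fraction of
daily primary production, but only part of the ingested biomass returns to
the lake (faeces, carcasses); the rest is metabolised or exported to the
terrestrial ecosystem. The export fraction of primary production is

    export = ingested × (1 − returned)

e.g. ingestion of 60% of daily primary production with one third returned
removes 40% of daily primary production from the aquatic food web.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["EnergyBudget", "export_fraction", "budget"]


def _check_fraction(x: float, name: str):
    if not (0.0 <= x <= 1.0):
        raise ValueError(f"{name} must be a fraction in [0, 1], got {x}")


def export_fraction(ingested: float, returned: float) -> float:
    """Fraction of daily primary production removed from the aquatic web."""
    _check_fraction(ingested, "ingested")
    _check_fraction(returned, "returned")
    return ingested * (1.0 - returned)


@dataclass(frozen=True)
class EnergyBudget:
    ingested: float      # fraction of daily primary production ingested
    returned: float      # fraction of ingested biomass returned to the lake
    export: float        # fraction of daily primary production exported

    def summary(self) -> str:
        return (
            f"ingested {self.ingested:.0%} of daily primary production, "
            f"{self.returned:.0%} of that returned -> "
            f"{self.export:.0%} of daily primary production removed "
            f"from the aquatic food web"
        )


def budget(ingested: float, returned: float) -> EnergyBudget:
    return EnergyBudget(ingested, returned, export_fraction(ingested, returned))
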