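"""Deterministic cost-and-time ledgers for the five calibration scenarios.

Costs are in location-specific phenotyping units: 1 X$ is the cost of one
full phenotype-evaluation trial (400 genotypes, 1200 plots) at a location;
a generation-advance trial (always at the surrogate location PAL) costs
0.4 X$_PAL.  Partial evaluations scale as the scenario states.  Totals are
exact decimal sums per currency; the two currencies are never added.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal

GENERATION_ADVANCE_COST = Decimal("0.4")

SCENARIOS = ("Uni1", "Uni2", "Uni3", "Multi1", "Multi2")


@dataclass(frozen=True)
class LedgerEntry:
    semester: str          # e.g. "Yr1-A"
    transition: str        # e.g. "S0:1->S0:2"
    fraction: str          # population fraction involved, e.g. "100%"
    activity: str          # generation_advance | phenotype_eval | gp_calibration
    location: str          # PAL | SRO
    cost: Decimal

    def __post_init__(self):
        if self.cost < 0:
            raise ValueError("costs must be >= 0")


@dataclass
class CostLedger:
    scenario: str
    entries: list = field(default_factory=list)
    semesters: int = 0
    years_to_calibration: float = 0.0

    def totals(self) -> dict:
        out = {"PAL": Decimal("0"), "SRO": Decimal("0")}
        for e in self.entries:
            out.setdefault(e.location, Decimal("0"))
            out[e.location] += e.cost
        return out

    def to_frame(self):
        import pandas as pd

        rows = [(e.semester, e.transition, e.fraction, e.activity, e.location,
                 str(e.cost)) for e in self.entries]
        return pd.DataFrame(rows, columns=["semester", "transition", "fraction",
                                           "activity", "location", "cost"])

    def render(self) -> str:
        lines = [f"Scenario {self.scenario} "
                 f"(calibration ready after {self.years_to_calibration} years)"]
        for e in self.entries:
            lines.append(f"  {e.semester:6s} {e.transition:12s} {e.fraction:>5s} "
                         f"{e.activity:18s} {e.location} {e.cost}X$_{e.location}")
        t = self.totals()
        lines.append(f"  total: {t['PAL']}X$_PAL + {t['SRO']}X$_SRO")
        return "\n".join(lines)


def _e(sem, tr, frac, act, loc, cost) -> LedgerEntry:
    return LedgerEntry(sem, tr, frac, act, loc, Decimal(cost))


_LEDGERS = {
    # three advance steps, then the full evaluation at the target site
    "Uni1": ([
        _e("Yr1-A", "S0:1->S0:2", "100%", "generation_advance", "PAL", "0.4"),
        _e("Yr1-B", "S0:2->S0:3", "100%", "generation_advance", "PAL", "0.4"),
        _e("Yr2-A", "S0:3->S0:4", "100%", "generation_advance", "PAL", "0.4"),
        _e("Yr3-A", "S0:4->S0:5", "100%", "phenotype_eval", "SRO", "1"),
    ], 5, 2.5),
    # early-generation evaluation; only selected families advanced afterwards
    "Uni2": ([
        _e("Yr1-A", "S0:1->S0:2", "100%", "generation_advance", "PAL", "0.4"),
        _e("Yr1-B", "S0:2->S0:3", "100%", "generation_advance", "PAL", "0.4"),
        _e("Yr2-A", "S0:2->S0:3", "100%", "phenotype_eval", "SRO", "1"),
        _e("Yr2-B", "S0:3->S0:4", "sel.", "generation_advance", "PAL", "0.05"),
    ], 3, 1.5),
    "Uni3": ([
        _e("Yr1-A", "S0:1->S0:2", "100%", "generation_advance", "PAL", "0.4"),
        _e("Yr1-B", "S0:2->S0:3", "100%", "generation_advance", "PAL", "0.4"),
        _e("Yr2-A", "S0:3->S0:4", "100%", "phenotype_eval", "SRO", "1"),
    ], 3, 1.5),
    "Multi1": ([
        _e("Yr1-A", "S0:1->S0:2", "100%", "generation_advance", "PAL", "0.4"),
        _e("Yr1-B", "S0:2->S0:3", "100%", "generation_advance", "PAL", "0.4"),
        _e("Yr2-A", "S0:3->S0:4", "100%", "generation_advance", "PAL", "0.4"),
        _e("Yr2-B", "S0:4->S0:5", "100%", "phenotype_eval", "PAL", "1"),
        _e("Yr3-A", "S0:4->S0:5", "100%", "phenotype_eval", "SRO", "1"),
    ], 5, 2.5),
    # surrogate-location evaluation doubles as seed multiplication; only half
    # the population is evaluated at the target site
    "Multi2": ([
        _e("Yr1-A", "S0:1->S0:2", "100%", "generation_advance", "PAL", "0.4"),
        _e("Yr1-B", "S0:2->S0:3", "100%", "phenotype_eval", "PAL", "1"),
        _e("Yr2-A", "S0:3->S0:4", "50%", "phenotype_eval", "SRO", "0.6"),
    ], 3, 1.5),
}


def scenario_ledger(name: str) -> CostLedger:
    """The built-in cost ledger of one of the five scenarios."""
    if name not in _LEDGERS:
        raise KeyError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    entries, semesters, years = _LEDGERS[name]
    return CostLedger(name, list(entries), semesters, years)


def custom_ledger(entries) -> dict:
    """Totals for a user-supplied entry list (same summation contract)."""
    ledger = CostLedger("custom", list(entries))
    return ledger.totals()
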