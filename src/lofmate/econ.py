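"""Breeding-program economics of lethal recessive alleles.

All accounting is per 100 matings.  An aa conception costs ``dead_cost``
(default $200); a genotype test costs ``test_cost`` (default $30); genotyping
pct% of the herd buys ``pct`` tests per 100 matings (the per-100-matings
test base recovered from the study's own savings/breakeven arithmetic).

* profit per mating: $P = $M - dead_cost x LethalG
* total loss: affected conceptions x dead_cost
* savings from genotyping: (base affected - affected at tier) x dead_cost
* net profit: savings - test_cost x n_tests
* breakeven test value: savings / n_tests

Reported dollars are rounded half-up to cents; computations keep full
precision internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

__all__ = [
    "EconConfig",
    "round_cents",
    "profit_per_mating",
    "total_loss",
    "savings",
    "net_profit",
    "breakeven",
]


@dataclass(frozen=True)
class EconConfig:
    dead_cost: float = 200.0  # $ per aa conception
    test_cost: float = 30.0  # $ per genotype test
    matings_per_run: int = 100

    def __post_init__(self) -> None:
        if self.dead_cost < 0 or self.test_cost < 0:
            raise ValueError("costs must be non-negative")

    def n_tests(self, pct: float) -> float:
        """Tests bought when genotyping pct% of the herd, per 100 matings."""
        if not 0 <= pct <= 100:
            raise ValueError("percentage must lie in [0, 100]")
        return pct * self.matings_per_run / 100.0


def round_cents(x: float) -> float:
    """Round half-up (away from zero) to cents, for reporting."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def profit_per_mating(mean_m: float, lethal_g: float, cfg: EconConfig = EconConfig(),
                      rounded: bool = True) -> float:
    """$P = $M - dead_cost x LethalG."""
    if not 0.0 <= lethal_g <= 1.0:
        raise ValueError("LethalG must be a probability")
    p = mean_m - cfg.dead_cost * lethal_g
    return round_cents(p) if rounded else p


def total_loss(affected_per_100: float, cfg: EconConfig = EconConfig(),
               rounded: bool = True) -> float:
    """Dollar loss per 100 matings from ``affected_per_100`` aa conceptions."""
    if affected_per_100 < 0:
        raise ValueError("affected count must be non-negative")
    v = affected_per_100 * cfg.dead_cost
    return round_cents(v) if rounded else v


def savings(base_affected: float, affected_at_tier: float,
            cfg: EconConfig = EconConfig(), rounded: bool = True) -> float:
    """Mortality cost avoided relative to the ungenotyped base run."""
    v = (base_affected - affected_at_tier) * cfg.dead_cost
    return round_cents(v) if rounded else v


def net_profit(savings_dollars: float, pct: float, cfg: EconConfig = EconConfig(),
               rounded: bool = True) -> float:
    """Savings minus genotyping costs at the tier: savings - test_cost x n_tests."""
    v = savings_dollars - cfg.test_cost * cfg.n_tests(pct)
    return round_cents(v) if rounded else v


def breakeven(savings_dollars: float, pct: float, cfg: EconConfig = EconConfig(),
              rounded: bool = True) -> float:
    """Test price at which genotyping pct% of the herd exactly pays for itself."""
    if pct <= 0:
        raise ValueError("breakeven undefined at 0% genotyped")
    v = savings_dollars / cfg.n_tests(pct)
    return round_cents(v) if rounded else v
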