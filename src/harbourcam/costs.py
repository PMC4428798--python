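"""Cost-effectiveness comparison: camera system vs personnel in the field.

Line items (gear, labour, expendables) are aggregated per method with exact
integer-cent arithmetic, and the minimum video-review time implied by
fast-playback perusal is computed from the playback speed factor.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .errors import DataError

METHODS = ("camera", "field")
CATEGORIES = ("gear", "labour", "expendables")


@dataclass(frozen=True)
class CostLineItem:
    method: str  # camera | field
    category: str  # gear | labour | expendables
    label: str
    amount_usd: Decimal  # carried exactly; stored internally as cents
    labour_hours: Optional[float] = None

    def __post_init__(self):
        if self.method not in METHODS:
            raise DataError(f"unknown method {self.method!r}")
        if self.category not in CATEGORIES:
            raise DataError(f"unknown category {self.category!r}")
        object.__setattr__(self, "amount_usd", Decimal(str(self.amount_usd)))
        if self.amount_usd < 0:
            raise DataError(f"negative amount for {self.label!r}")
        if self.labour_hours is not None and self.labour_hours < 0:
            raise DataError(f"negative hours for {self.label!r}")

    @property
    def amount_cents(self) -> int:
        return int((self.amount_usd * 100).to_integral_value(rounding=ROUND_HALF_UP))


# Default line items for a 42-day dual-method shore-based dolphin-monitoring
# campaign (USD): one camera rig on a harbour tower vs a two-person field
# team with theodolite and binoculars.  Overheads and on-costs excluded.
DEFAULT_COST_ITEMS = [
    CostLineItem("camera", "gear", "Gear", Decimal("5014")),
    CostLineItem("camera", "labour", "Labour gear preparation", Decimal("5900"), 35.0),
    CostLineItem("camera", "labour", "Labour field servicing", Decimal("3471"), 20.0),
    CostLineItem("camera", "labour", "Labour photogrammetry programming", Decimal("2647"), 17.0),
    CostLineItem("camera", "labour", "Labour video perusing", Decimal("12247"), 418.0),
    CostLineItem("camera", "expendables", "Expendables (batteries, hard drives, SD cards)", Decimal("1206")),
    CostLineItem("field", "gear", "Gear", Decimal("10359")),
    CostLineItem("field", "labour", "Labour", Decimal("36280"), 588.0),
    CostLineItem("field", "expendables", "Expendables", Decimal("941")),
]


@dataclass
class CostComparison:
    totals_usd: dict  # method -> Decimal
    subtotals_usd: dict  # (method, category) -> Decimal
    hours: dict  # method -> float
    difference_usd: dict  # category -> Decimal (field - camera)
    ratio: dict  # category -> float or None when the denominator is zero

    def table(self) -> pd.DataFrame:
        rows = []
        for m in METHODS:
            for c in CATEGORIES:
                rows.append(
                    {"method": m, "category": c, "subtotal_usd": float(self.subtotals_usd[(m, c)])}
                )
            rows.append(
                {"method": m, "category": "total", "subtotal_usd": float(self.totals_usd[m])}
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = []
        for m in METHODS:
            lines.append(
                f"{m} method: USD ${self.totals_usd[m]:,} total, "
                f"{self.hours[m]:.0f} labour hours"
            )
        big = max(CATEGORIES, key=lambda c: abs(self.difference_usd[c]))
        lines.append(
            f"largest cost difference is in {big}: USD ${self.difference_usd[big]:,}"
        )
        return "\n".join(lines)


def summarise_costs(items: Sequence[CostLineItem]) -> CostComparison:
    """Per-method totals, per-category subtotals, hours, differences, ratios.

    Amounts are summed in integer cents, so the totals are exact and
    order-invariant.
    """
    for m in METHODS:
        if not any(it.method == m for it in items):
            raise DataError(f"no line items for the {m!r} method")
    sub_cents = {(m, c): 0 for m in METHODS for c in CATEGORIES}
    hours = {m: 0.0 for m in METHODS}
    for it in items:
        sub_cents[(it.method, it.category)] += it.amount_cents
        if it.labour_hours is not None:
            hours[it.method] += it.labour_hours
    totals = {
        m: Decimal(sum(sub_cents[(m, c)] for c in CATEGORIES)) / 100 for m in METHODS
    }
    subtotals = {k: Decimal(v) / 100 for k, v in sub_cents.items()}
    diff = {
        c: subtotals[("field", c)] - subtotals[("camera", c)] for c in CATEGORIES
    }
    ratio = {
        c: (
            float(subtotals[("field", c)] / subtotals[("camera", c)])
            if subtotals[("camera", c)] > 0
            else None
        )
        for c in CATEGORIES
    }
    return CostComparison(
        totals_usd=totals,
        subtotals_usd=subtotals,
        hours=hours,
        difference_usd=diff,
        ratio=ratio,
    )


def perusal_time(
    footage_hours: float, speed_factor: float = 1.75, overhead_fraction: float = 0.0
) -> tuple[float, int]:
    """Minimum review time for fast-playback video perusal.

    Returns ``(hours, whole_hours)``: the exact review time
    ``footage / speed * (1 + overhead)`` and a round-half-up whole-hour
    convenience value.  ``overhead_fraction`` covers rewinding, pausing and
    normal-speed rechecking.
    """
    if speed_factor < 1:
        raise ValueError("speed_factor must be >= 1")
    if footage_hours < 0:
        raise ValueError("footage_hours must be >= 0")
    hours = footage_hours / speed_factor * (1.0 + overhead_fraction)
    whole = int(Decimal(str(hours)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))
    return hours, whole


def read_cost_csv(path) -> list:
    """Line items from a CSV with columns method,category,label,amount_usd[,labour_hours]."""
    df = pd.read_csv(Path(path))
    items = []
    for _, r in df.iterrows():
        hrs = r.get("labour_hours")
        items.append(
            CostLineItem(
                method=r["method"],
                category=r["category"],
                label=r["label"],
                amount_usd=Decimal(str(r["amount_usd"])),
                labour_hours=None if pd.isna(hrs) else float(hrs),
            )
        )
    return items


def write_cost_csv(items: Sequence[CostLineItem], path) -> None:
    pd.DataFrame(
        [
            {
                "method": it.method,
                "category": it.category,
                "label": it.label,
                "amount_usd": float(it.amount_usd),
                "labour_hours": it.labour_hours,
            }
            for it in items
        ]
    ).to_csv(path, index=False)
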