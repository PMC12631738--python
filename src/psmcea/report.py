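"""Result-table assembly with exact aggregation arithmetic.

Totals are component sums and incrementals are arm differences, all computed
at full precision; the ICER is computed from unrounded deltas.  Rounding
(half away from zero, two decimals) is applied only when rendering.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .cea import COMPARATOR, INTERVENTION, CEAResult, compare
from .valuation import ArmResult

__all__ = ["ReportTable", "assemble_report", "round_half_away"]


def round_half_away(x: float, decimals: int = 2) -> float:
    """Round half away from zero (display convention for all tables)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


_ROWS = (
    ("cost_pfs", "Cost, PFS"),
    ("cost_pd", "Cost, PD"),
    ("cost_death", "Cost, Death"),
    ("cost_total", "Cost, Total"),
    ("qaly_pfs", "QALY, PFS"),
    ("qaly_pd", "QALY, PD"),
    ("qaly_total", "QALY, Total"),
    ("ly_pfs", "LY, PFS"),
    ("ly_pd", "LY, PD"),
    ("ly_total", "LY, Total"),
)


@dataclass(frozen=True)
class ReportTable:
    """Per-population, per-arm state-split results plus incrementals."""

    populations: dict[str, dict[str, ArmResult]]
    incrementals: dict[str, CEAResult]
    wtp: float

    def to_frame(self) -> pd.DataFrame:
        """Unrounded long-format table (one row per population/quantity)."""
        rows = []
        for pop, arms in self.populations.items():
            inc = self.incrementals[pop]
            for attr, label in _ROWS:
                rows.append(
                    {
                        "population": pop,
                        "quantity": label,
                        INTERVENTION: getattr(arms[INTERVENTION], attr),
                        COMPARATOR: getattr(arms[COMPARATOR], attr),
                    }
                )
            for label, value in (
                ("Incremental cost", inc.delta_cost),
                ("Incremental QALY", inc.delta_qaly),
                ("Incremental LY", inc.delta_ly),
                ("ICER", inc.icer),
                ("NMB", inc.nmb),
            ):
                rows.append(
                    {"population": pop, "quantity": label, INTERVENTION: value, COMPARATOR: None}
                )
        return pd.DataFrame(rows)

    def rendered(self) -> pd.DataFrame:
        """Display table rounded half-away-from-zero to two decimals."""
        df = self.to_frame().copy()
        for col in (INTERVENTION, COMPARATOR):
            df[col] = df[col].map(
                lambda v: round_half_away(v) if v is not None and pd.notna(v) else None
            )
        return df

    def to_markdown(self) -> str:
        lines = []
        for pop in self.populations:
            inc = self.incrementals[pop]
            lines.append(f"## Population: {pop}")
            lines.append("")
            lines.append(f"| Quantity | {INTERVENTION} | {COMPARATOR} |")
            lines.append("| --- | ---: | ---: |")
            sub = self.rendered()
            sub = sub[sub["population"] == pop]
            for _, row in sub.iterrows():
                a = "" if pd.isna(row[INTERVENTION]) else f"{row[INTERVENTION]:,.2f}"
                b = "" if pd.isna(row[COMPARATOR]) else f"{row[COMPARATOR]:,.2f}"
                lines.append(f"| {row['quantity']} | {a} | {b} |")
            if inc.label:
                lines.append("")
                lines.append(f"The intervention is **{inc.label}**.")
            lines.append("")
        return "\n".join(lines)


def assemble_report(results: dict[str, dict[str, ArmResult]], wtp: float) -> ReportTable:
    """Build the results table from per-arm results keyed by population.

    ``results`` maps population label to ``{"PEM": ArmResult, "TRAS": ArmResult}``.
    """
    incrementals = {}
    for pop, arms in results.items():
        for arm in (INTERVENTION, COMPARATOR):
            if arm not in arms:
                raise ValueError(f"population {pop!r} is missing arm {arm}")
        incrementals[pop] = compare(arms[INTERVENTION], arms[COMPARATOR], wtp)
    return ReportTable(results, incrementals, wtp)
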