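"""Descriptive utilization layer: prevalence-ranked tables and size distribution.

Prevalence of an item is the fraction of all retained prescriptions that
contain it (identical to its size-1 itemset support in the mining stage);
dose and duration are averaged over the prescriptions containing the item.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .claims import VisitRecord
from .mining import round_half_up

__all__ = [
    "PrevalenceRow",
    "SizeDistribution",
    "prevalence_table",
    "size_distribution",
]


@dataclass(frozen=True)
class PrevalenceRow:
    rank: int
    code: str
    name: str
    kind: str
    prevalence: float
    mean_dose_g_per_day: float
    mean_duration_days: float


@dataclass(frozen=True)
class SizeDistribution:
    """Distribution of distinct-item counts per prescription."""

    histogram: Mapping[int, float]
    mean: float

    def modal_size(self) -> int:
        return max(self.histogram, key=lambda k: (self.histogram[k], -k))


def prevalence_table(
    visits: Sequence[VisitRecord],
    kind: str = "all",
    top_n: int | None = None,
) -> list[PrevalenceRow]:
    """Prevalence-ranked item table with per-prescription dose/duration means.

    ``kind`` restricts to herbal formulas ("HF"), single herbs ("SH") or
    everything ("all").  ``top_n`` is a display cut; the full ranking is
    returned when omitted.  Ties are broken by code for a stable order.
    """
    if not visits:
        raise ValueError("no visits")
    n = len(visits)
    stats: dict[str, dict] = {}
    for v in visits:
        for item in v.items:
            s = stats.setdefault(
                item.code,
                {"name": item.name, "kind": item.kind, "count": 0, "dose": 0.0, "dur": 0.0},
            )
            s["count"] += 1
            s["dose"] += item.dose_g_per_day
            s["dur"] += item.duration_days
    if kind != "all":
        stats = {c: s for c, s in stats.items() if s["kind"] == kind}
    ranked = sorted(stats.items(), key=lambda kv: (-kv[1]["count"], kv[0]))
    rows = [
        PrevalenceRow(
            rank=i + 1,
            code=code,
            name=s["name"],
            kind=s["kind"],
            prevalence=s["count"] / n,
            mean_dose_g_per_day=s["dose"] / s["count"],
            mean_duration_days=s["dur"] / s["count"],
        )
        for i, (code, s) in enumerate(ranked)
    ]
    return rows[:top_n] if top_n is not None else rows


def prevalence_to_frame(rows: Sequence[PrevalenceRow]) -> pd.DataFrame:
    """Report view at the precision of printed utilization tables."""
    return pd.DataFrame(
        {
            "rank": [r.rank for r in rows],
            "code": [r.code for r in rows],
            "name": [r.name for r in rows],
            "kind": [r.kind for r in rows],
            "prevalence_pct": [round_half_up(100 * r.prevalence, 1) for r in rows],
            "dose_g_per_day": [round_half_up(r.mean_dose_g_per_day, 2) for r in rows],
            "duration_days": [round_half_up(r.mean_duration_days, 1) for r in rows],
        }
    )


def size_distribution(visits: Sequence[VisitRecord]) -> SizeDistribution:
    """Histogram (fractions) and mean of distinct items per prescription."""
    if not visits:
        raise ValueError("no visits")
    sizes = np.array([len(v.item_codes) for v in visits])
    values, counts = np.unique(sizes, return_counts=True)
    frac = counts / counts.sum()
    return SizeDistribution(
        histogram={int(v): float(f) for v, f in zip(values, frac)},
        mean=float(sizes.mean()),
    )
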