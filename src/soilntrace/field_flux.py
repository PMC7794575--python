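"""Runoff NO3- loss accounting.

Each runoff event contributes ``c * q / 100`` kg N ha^-1, where ``c`` is the
event NO3- concentration of the water sample (mg L^-1) and ``q`` the event
discharge depth (mm); the /100 factor is the literal mg L^-1 x mm ->
kg ha^-1 unit conversion.  The annual loss flux Q is the sum over events.
Interflow and overland-runoff events are kept as separate pathways and
summed; a whole-catchment weir series carries its own pathway label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = ["PATHWAYS", "RunoffEvent", "FluxResult", "annual_no3_flux"]

PATHWAYS = ("interflow", "overland", "whole-catchment")


@dataclass(frozen=True)
class RunoffEvent:
    """One monitored runoff event."""

    date: str
    c: float  # NO3- concentration, mg L^-1
    q: float  # discharge depth, mm
    pathway: str = "whole-catchment"

    def __post_init__(self) -> None:
        if self.c < 0:
            raise ValueError(f"negative concentration {self.c} on {self.date}")
        if self.q < 0:
            raise ValueError(f"negative discharge {self.q} on {self.date}")
        if self.pathway not in PATHWAYS:
            raise ValueError(
                f"unknown pathway {self.pathway!r}; expected one of {PATHWAYS}"
            )

    @property
    def contribution(self) -> float:
        """Event NO3- loss, kg N ha^-1."""
        return self.c * self.q / 100.0


@dataclass(frozen=True)
class FluxResult:
    """Annual NO3- loss flux with per-event and per-pathway breakdown."""

    total: float  # kg N ha^-1 year^-1
    n_events: int
    contributions: tuple[float, ...]
    by_pathway: dict[str, float] = field(default_factory=dict)

    def as_frame(self) -> pd.DataFrame:
        rows = [{"pathway": p, "q_kg_n_ha": v} for p, v in sorted(self.by_pathway.items())]
        rows.append({"pathway": "total", "q_kg_n_ha": self.total})
        return pd.DataFrame(rows)


def annual_no3_flux(events: Iterable[RunoffEvent]) -> FluxResult:
    """Aggregate runoff events into the annual NO3- loss flux
    Q = sum_i c_i * q_i / 100 (kg N ha^-1 year^-1)."""
    events = list(events)
    contribs = tuple(e.contribution for e in events)
    by_pathway: dict[str, float] = {}
    for e in events:
        by_pathway[e.pathway] = by_pathway.get(e.pathway, 0.0) + e.contribution
    return FluxResult(
        total=sum(contribs),
        n_events=len(events),
        contributions=contribs,
        by_pathway=by_pathway,
    )


def events_from_frame(frame: pd.DataFrame) -> list[RunoffEvent]:
    """Build events from a table with columns date, pathway, c_mg_per_L, q_mm."""
    required = {"date", "pathway", "c_mg_per_L", "q_mm"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"event table missing columns {sorted(missing)}")
    out = []
    for i, row in frame.iterrows():
        try:
            out.append(
                RunoffEvent(
                    date=str(row["date"]),
                    c=float(row["c_mg_per_L"]),
                    q=float(row["q_mm"]),
                    pathway=str(row["pathway"]),
                )
            )
        except ValueError as exc:
            raise ValueError(f"row {i + 1}: {exc}") from exc
    return out
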