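"""Ventilation episodes, event definitions, eligibility and labels.

The prediction target is *unplanned intubation in the next horizon*
(12 h by default, 4 h in sensitivity analysis).  A window (stamped by
its end time t) is a case when an unplanned intubation occurs in
(t, t + horizon]; every other eligible window is a control, including
windows from event admissions outside the pre-event period.

A patient is at risk only while in the PICU and not already on the
ventilator.  Mechanical ventilation is phenotyped from the ventilator
respiratory rate: an episode runs from the first to the last ventilator
RR in a run, with runs split whenever consecutive measurements are more
than 12 h apart.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "VentilationEpisode",
    "ventilation_episodes",
    "unplanned_events",
    "apply_exclusions",
    "eligibility",
    "label",
    "patient_type",
    "HORIZON_12H_S",
    "HORIZON_4H_S",
]

HORIZON_12H_S = 12 * 3600
HORIZON_4H_S = 4 * 3600
VENT_GAP_S = 12 * 3600
ADMIT_EXCLUSION_S = 15 * 60
EXTUBATION_EXCLUSION_S = 3600


@dataclass(frozen=True)
class VentilationEpisode:
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("episode end before start")


def ventilation_episodes(vent_rr_times: np.ndarray,
                         *, gap_s: float = VENT_GAP_S) -> list[VentilationEpisode]:
    """Split sorted ventilator-RR timestamps into ventilation episodes.

    Runs split strictly at gaps > ``gap_s`` (a gap of exactly 12 h stays
    one episode); a single measurement yields a zero-length episode.
    """
    t = np.asarray(vent_rr_times, dtype=float)
    if t.size == 0:
        return []
    if np.any(np.diff(t) < 0):
        raise ValueError("ventilator RR times must be sorted")
    breaks = np.nonzero(np.diff(t) > gap_s)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [t.size - 1]])
    return [VentilationEpisode(float(t[i]), float(t[j]))
            for i, j in zip(starts, ends)]


def unplanned_events(events: pd.DataFrame, mode: str) -> pd.DataFrame:
    """Select intubation events under either event definition.

    ``chart_review`` keeps non-elective, in-PICU intubations (the
    registry-reviewed phenotype); ``computable_phenotype`` keeps every
    recorded intubation regardless of location or indication.  The
    chart-review set is always a subset of the computable-phenotype set.
    """
    if mode not in ("chart_review", "computable_phenotype"):
        raise ValueError(f"unknown event definition mode: {mode!r}")
    ev = events[events["kind"] == "intubation"]
    if mode == "chart_review":
        ev = ev[(~ev["elective"].astype(bool)) & ev["in_picu"].astype(bool)]
    return ev.reset_index(drop=True)


def apply_exclusions(events: pd.DataFrame, picu_intervals: list[tuple[float, float]],
                     extubation_times: np.ndarray,
                     *, admit_s: float = ADMIT_EXCLUSION_S,
                     extub_s: float = EXTUBATION_EXCLUSION_S) -> pd.DataFrame:
    """Drop peri-admission and post-extubation intubations.

    Intubations within 15 min after a PICU-interval start, or within 1 h
    after a prior extubation, are excluded (half-open intervals measured
    forward from the triggering event).
    """
    ext = np.sort(np.asarray(extubation_times, dtype=float))
    keep = []
    for _, ev in events.iterrows():
        t = float(ev["time_s"])
        near_admit = any(start <= t < start + admit_s
                         for start, _ in picu_intervals)
        prior = ext[ext <= t]
        near_extub = prior.size > 0 and (t - prior[-1]) < extub_s
        keep.append(not (near_admit or near_extub))
    return events[np.asarray(keep, dtype=bool)].reset_index(drop=True)


def eligibility(window_times: np.ndarray,
                picu_intervals: list[tuple[float, float]],
                vent_episodes: list[VentilationEpisode]) -> np.ndarray:
    """At-risk flags: in the PICU and outside every ventilation episode."""
    t = np.asarray(window_times, dtype=float)
    in_picu = np.zeros(t.shape, dtype=bool)
    for start, end in picu_intervals:
        in_picu |= (t >= start) & (t < end)
    ventilated = np.zeros(t.shape, dtype=bool)
    for ep in vent_episodes:
        ventilated |= (t >= ep.start) & (t <= ep.end)
    return in_picu & ~ventilated


def label(window_times: np.ndarray, eligible: np.ndarray,
          event_times: np.ndarray, horizon_s: float) -> pd.DataFrame:
    """Case/control labels for one admission's windows.

    A window at time t is a case when it is eligible and some (already
    filtered) event satisfies t < event_time <= t + horizon; multiple
    events are independent, and ``event_id`` records the *earliest*
    qualifying event for each case window.
    """
    if horizon_s <= 0:
        raise ValueError("horizon must be positive")
    t = np.asarray(window_times, dtype=float)
    elig = np.asarray(eligible, dtype=bool)
    ev = np.sort(np.asarray(event_times, dtype=float))
    is_case = np.zeros(t.shape, dtype=bool)
    event_id = np.full(t.shape, -1, dtype=int)
    for i, e in enumerate(ev):
        hit = elig & (t < e) & (e <= t + horizon_s)
        event_id[hit & ~is_case] = i
        is_case |= hit
    return pd.DataFrame({
        "t": t.astype(int),
        "eligible": elig,
        "label": np.where(is_case, "case", "control"),
        "event_id": event_id,
    })


def patient_type(or_records: pd.DataFrame) -> str:
    """Classify an admission from its operating-room records.

    No OR record -> medical; any thoracic-cardiovascular OR record ->
    cardiac surgery (dominating all others); otherwise non-cardiac
    surgery.
    """
    if len(or_records) == 0:
        return "medical"
    if (or_records["service"] == "thoracic_cardiovascular").any():
        return "cardiac_surgery"
    return "noncardiac_surgery"
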