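"""Reconstruction of patch trajectories from RFID detection streams.

Turns raw antenna reads into deduplicated events, completed patch-to-patch
crossings, and per-replicate occupancy step functions (patch counts and sex
ratios over time).  The antenna geometry is two patches joined by a corridor
with one antenna near each patch mouth: a crossing shows up as a near-antenna
read followed by a far-antenna read; a same-antenna pair is an aborted
corridor entry; a trailing unpaired read is an unresolved corridor entry and
yields no crossing.

Timestamps are integer seconds with 0 = darkness onset; step functions are
piecewise constant on half-open intervals [start, end).  Occupancy follows
the last-known-patch convention: every individual is assigned to a patch at
all times and its assignment flips at the read that completes a crossing.
This is exactly what the detection record can support — between the near and
far reads the animal's position is unobservable, so densities and sex ratios
are bookkept by last known patch and x_1(t) + x_2(t) = N throughout (the
corridor series is identically zero and is kept only for interface
completeness).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EVENT_COLUMNS = ["replicate_id", "tag_id", "antenna", "timestamp_s"]
ROSTER_COLUMNS = ["tag_id", "sex", "replicate_id", "release_patch"]
CROSSING_COLUMNS = ["replicate_id", "tag_id", "direction", "start_s", "end_s",
                    "duration_s"]
PATCH_FOR_ANTENNA = {"A1": 1, "A2": 2}


class ReconstructionError(ValueError):
    """Inconsistent event stream under strict checking."""


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def sort_events(events: pd.DataFrame) -> pd.DataFrame:
    """Stable sort by (replicate, timestamp, tag, antenna)."""
    return events.sort_values(
        ["replicate_id", "timestamp_s", "tag_id", "antenna"], kind="stable"
    ).reset_index(drop=True)


def read_events(path, roster_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read detections.csv and individuals.csv, validate, and sort.

    Raises on malformed rows (with the offending line number) and on event
    tags missing from the roster (naming the tag).
    """
    events = pd.read_csv(path, dtype={"replicate_id": str, "tag_id": str,
                                      "antenna": str})
    roster = pd.read_csv(roster_path, dtype={"replicate_id": str,
                                             "tag_id": str, "sex": str})
    for col in EVENT_COLUMNS:
        if col not in events.columns:
            raise ValueError(f"detections file {path}: missing column {col!r}")
    for col in ROSTER_COLUMNS:
        if col not in roster.columns:
            raise ValueError(f"roster file {roster_path}: missing column {col!r}")

    bad_ant = ~events["antenna"].isin(PATCH_FOR_ANTENNA)
    if bad_ant.any():
        line = int(events.index[bad_ant][0]) + 2  # header + 1-based
        raise ValueError(
            f"{path}: line {line}: antenna must be A1 or A2, "
            f"got {events.loc[events.index[bad_ant][0], 'antenna']!r}"
        )
    ts = pd.to_numeric(events["timestamp_s"], errors="coerce")
    if ts.isna().any():
        line = int(events.index[ts.isna()][0]) + 2
        raise ValueError(f"{path}: line {line}: non-numeric timestamp")
    events["timestamp_s"] = ts.astype(np.int64)

    unknown = set(events["tag_id"]) - set(roster["tag_id"])
    if unknown:
        raise ValueError(f"event tag(s) not in roster: {sorted(unknown)[:5]}")
    return sort_events(events), roster.reset_index(drop=True)


def write_events(events: pd.DataFrame, path) -> None:
    events.to_csv(path, index=False, columns=EVENT_COLUMNS)


# ---------------------------------------------------------------------------
# deduplication
# ---------------------------------------------------------------------------

def dedup_events(events: pd.DataFrame, window_s: int = 60) -> pd.DataFrame:
    """Apply the reader's dead time: within each (replicate, tag, antenna),
    drop any event less than ``window_s`` after the previously *retained*
    event of that pair.  Idempotent."""
    if events.empty:
        return events.reset_index(drop=True)
    ts = events["timestamp_s"].to_numpy()
    keep = np.ones(len(events), dtype=bool)
    groups = events.groupby(
        ["replicate_id", "tag_id", "antenna"], sort=False
    ).indices
    for idx in groups.values():
        idx = np.sort(idx)
        last = None
        for k in idx:
            if last is not None and ts[k] - last < window_s:
                keep[k] = False
            else:
                last = ts[k]
    return events.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# crossing inference
# ---------------------------------------------------------------------------

def infer_crossings(
    events: pd.DataFrame,
    roster: pd.DataFrame,
    strict: bool = True,
) -> pd.DataFrame:
    """Pair antenna reads into completed crossings.

    Scans each agent's deduplicated event sequence: a consecutive pair on
    different antennas is a completed crossing (direction from the agent's
    current patch toward the other, start and end at the two reads); a
    same-antenna pair is an aborted corridor entry (the agent stays); a
    trailing unpaired read is an unresolved corridor entry.

    With ``strict=True`` a read at the antenna not adjacent to the agent's
    current patch raises :class:`ReconstructionError`; with ``strict=False``
    the agent's state is resynchronised to that antenna's patch with a
    warning.
    """
    release = dict(zip(roster["tag_id"], roster["release_patch"].astype(int)))
    rows: list[tuple] = []
    if not events.empty:
        for (rep, tag), grp in events.groupby(["replicate_id", "tag_id"],
                                              sort=False):
            cur = release[tag]
            ants = grp["antenna"].tolist()
            times = grp["timestamp_s"].tolist()
            i = 0
            while i + 1 < len(ants):
                near = PATCH_FOR_ANTENNA[ants[i]]
                if near != cur:
                    if strict:
                        raise ReconstructionError(
                            f"replicate {rep}, tag {tag}: read at {ants[i]} "
                            f"(t={times[i]}) but agent is in patch {cur}"
                        )
                    logger.warning(
                        "replicate %s tag %s: resynchronising patch %d -> %d "
                        "at t=%d", rep, tag, cur, near, times[i],
                    )
                    cur = near
                if ants[i + 1] == ants[i]:  # aborted entry, agent stays
                    i += 2
                    continue
                target = 3 - cur
                rows.append((rep, tag, f"{cur}->{target}", times[i],
                             times[i + 1], times[i + 1] - times[i]))
                cur = target
                i += 2
    crossings = pd.DataFrame(rows, columns=CROSSING_COLUMNS)
    return crossings.sort_values(
        ["replicate_id", "start_s", "tag_id"], kind="stable"
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# occupancy step functions
# ---------------------------------------------------------------------------

class StepFunction:
    """Right-continuous piecewise-constant function on [0, horizon).

    ``times`` are change points starting at 0; ``values[k]`` holds on
    ``[times[k], times[k+1])``.
    """

    def __init__(self, times: np.ndarray, values: np.ndarray, horizon: float):
        self.times = np.asarray(times, dtype=float)
        self.values = np.asarray(values, dtype=float)
        self.horizon = float(horizon)
        if self.times[0] != 0 or len(self.times) != len(self.values):
            raise ValueError("step function needs times[0]=0 and equal lengths")
        edges = np.append(self.times, self.horizon)
        self._cum = np.concatenate(
            ([0.0], np.cumsum(self.values * np.diff(edges)))
        )

    def __call__(self, t):
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float),
                              side="right") - 1
        out = self.values[idx]
        return float(out) if np.ndim(t) == 0 else out

    def _integral_to(self, t: np.ndarray) -> np.ndarray:
        t = np.clip(t, 0.0, self.horizon)
        idx = np.searchsorted(self.times, t, side="right") - 1
        return self._cum[idx] + self.values[idx] * (t - self.times[idx])

    def mean(self, a, b):
        """Time-weighted mean over [a, b)."""
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        out = (self._integral_to(b) - self._integral_to(a)) / (b - a)
        return float(out) if out.ndim == 0 else out


@dataclass
class ReplicateOccupancy:
    """Step-function view of one replicate's patch system."""

    replicate_id: str
    n_agents: int
    night_s: int
    density: dict[int, StepFunction]        # patch -> count of occupants
    male_count: dict[int, StepFunction]
    sex_ratio: dict[int, StepFunction]      # males/total, empty-patch value
    corridor: StepFunction                  # agents in transit
    agent_label_times: dict[str, np.ndarray]   # completion times per agent
    agent_label_values: dict[str, np.ndarray]  # patch label after each time

    def agent_patch(self, tag_id: str, t: float) -> int:
        """Patch label of an agent at time t (origin patch during transit)."""
        times = self.agent_label_times[tag_id]
        idx = int(np.searchsorted(times, t, side="right")) - 1
        return int(self.agent_label_values[tag_id][idx])


class OccupancySeries(dict):
    """Mapping replicate_id -> :class:`ReplicateOccupancy`."""


def build_occupancy(
    crossings: pd.DataFrame,
    roster: pd.DataFrame,
    night_length_min: int = 720,
    empty_patch_sex_ratio: float = 0.5,
) -> OccupancySeries:
    """Build per-replicate occupancy/density/sex-ratio step functions.

    A 1->2 crossing ending at t* moves the agent from patch 1 to patch 2
    exactly at t*: x_1 drops by one and x_2 rises by one at the completion
    read (last-known-patch accounting).  An empty patch's sex ratio takes
    the configured convention value.
    """
    night_s = night_length_min * 60
    out = OccupancySeries()
    for rep, ros in roster.groupby("replicate_id", sort=False):
        cross = crossings[crossings["replicate_id"] == rep]
        male = dict(zip(ros["tag_id"], ros["sex"] == "M"))
        release = dict(zip(ros["tag_id"], ros["release_patch"].astype(int)))

        # (time, patch, dn, dm) deltas; order within a tie: departures first
        deltas: list[tuple[int, int, int, int]] = []
        label_times: dict[str, list] = {t: [0] for t in ros["tag_id"]}
        label_vals: dict[str, list] = {t: [release[t]] for t in ros["tag_id"]}
        in_corridor_until: dict[str, int] = {}
        for row in cross.sort_values(["start_s", "end_s"]).itertuples():
            tag = row.tag_id
            origin, target = (int(x) for x in row.direction.split("->"))
            if tag in in_corridor_until and row.start_s < in_corridor_until[tag]:
                raise ReconstructionError(
                    f"replicate {rep}, tag {tag}: crossing at t={row.start_s} "
                    "while still mid-corridor"
                )
            cur = label_vals[tag][-1]
            if origin != cur:
                raise ReconstructionError(
                    f"replicate {rep}, tag {tag}: crossing direction "
                    f"{row.direction} inconsistent with patch {cur}"
                )
            m = int(male[tag])
            deltas.append((int(row.end_s), origin, -1, -m))
            deltas.append((int(row.end_s), target, +1, +m))
            in_corridor_until[tag] = int(row.end_s)
            label_times[tag].append(int(row.end_s))
            label_vals[tag].append(target)

        n0 = {p: sum(1 for t in ros["tag_id"] if release[t] == p) for p in (1, 2)}
        m0 = {p: sum(1 for t in ros["tag_id"] if release[t] == p and male[t])
              for p in (1, 2)}
        times = sorted({0} | {d[0] for d in deltas})
        times = [t for t in times if t < night_s] or [0]
        tarr = np.asarray(times, dtype=float)
        counts = {p: np.zeros(len(times)) for p in (1, 2)}
        males = {p: np.zeros(len(times)) for p in (1, 2)}
        cur_n = dict(n0)
        cur_m = dict(m0)
        pos = {t: k for k, t in enumerate(times)}
        for p in (1, 2):
            counts[p][:] = cur_n[p]
            males[p][:] = cur_m[p]
        for t_ev, p, dn, dm in sorted(deltas):
            if t_ev >= night_s:
                continue
            k = pos[t_ev]
            counts[p][k:] += dn
            males[p][k:] += dm

        density = {p: StepFunction(tarr, counts[p], night_s) for p in (1, 2)}
        male_ct = {p: StepFunction(tarr, males[p], night_s) for p in (1, 2)}
        sr = {}
        for p in (1, 2):
            with np.errstate(invalid="ignore", divide="ignore"):
                vals = np.where(counts[p] > 0,
                                males[p] / np.maximum(counts[p], 1),
                                empty_patch_sex_ratio)
            sr[p] = StepFunction(tarr, vals, night_s)
        corridor = StepFunction(
            tarr, len(ros) - counts[1] - counts[2], night_s)

        out[rep] = ReplicateOccupancy(
            replicate_id=rep,
            n_agents=len(ros),
            night_s=night_s,
            density=density,
            male_count=male_ct,
            sex_ratio=sr,
            corridor=corridor,
            agent_label_times={t: np.asarray(v, dtype=float)
                               for t, v in label_times.items()},
            agent_label_values={t: np.asarray(v, dtype=int)
                                for t, v in label_vals.items()},
        )
    return out


def occupancy_frame(series: OccupancySeries) -> pd.DataFrame:
    """Long-format change points: replicate, time_s, patch, density, sex_ratio."""
    rows = []
    for rep, occ in series.items():
        for p in (1, 2):
            sf = occ.density[p]
            sr = occ.sex_ratio[p]
            for t, v in zip(sf.times, sf.values):
                rows.append((rep, int(t), p, float(v), float(sr(t))))
    return pd.DataFrame(
        rows, columns=["replicate_id", "time_s", "patch", "density",
                       "sex_ratio"]
    ).sort_values(["replicate_id", "time_s", "patch"]).reset_index(drop=True)
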