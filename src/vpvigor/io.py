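"""Session bundle IO.

A *session bundle* is the on-disk unit of one recording session: two-LED head
tracking at a fixed frame rate, a behavioral event log (cue onsets/offsets,
lever presses, receptacle entries, rewards, optional infusion marker),
per-neuron spike timestamp lists, and a JSON manifest describing the arena
geometry and session epochs.  All times are seconds from session start; frame
``k`` of the tracking series has time ``k / frame_rate``.

Formats (CSV, comma-separated, header row, UTF-8, '.' decimal, 6 decimal
places on write):

* ``tracking.csv``: ``frame,time_s,red_x_mm,red_y_mm,green_x_mm,green_y_mm``
  (missing LED samples are empty fields),
* ``events.csv``: ``time_s,kind,payload``,
* ``spikes.csv``: ``neuron_id,time_s``,
* ``manifest.json``: ``frame_rate_hz, duration_s, arena_mm, lever_xy_mm,
  receptacle_xy_mm, subject_id, session_id, infusion_time_s,
  infusion_condition``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

EVENT_KINDS = frozenset(
    {
        "DS_on",
        "DS_off",
        "NS_on",
        "NS_off",
        "active_press",
        "inactive_press",
        "port_entry",
        "reward",
        "infusion",
    }
)

CUE_MAX_LENGTH_S = 10.0


class SessionLoadError(Exception):
    """A required file is missing or a row cannot be parsed."""


class SessionValidationError(Exception):
    """A bundle violates a structural invariant."""


@dataclass
class TrackingSeries:
    """Two-LED head tracking at a fixed frame rate.

    Coordinates are mm in the arena frame; missing samples are NaN.
    """

    frame_index: np.ndarray
    red_xy: np.ndarray  # (n, 2), NaN where the LED was lost
    green_xy: np.ndarray  # (n, 2)
    frame_rate: float

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        self.red_xy = np.asarray(self.red_xy, dtype=float).reshape(-1, 2)
        self.green_xy = np.asarray(self.green_xy, dtype=float).reshape(-1, 2)

    @property
    def time(self) -> np.ndarray:
        return self.frame_index / self.frame_rate

    @property
    def n_frames(self) -> int:
        return len(self.frame_index)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TrackingSeries):
            return NotImplemented
        return (
            np.array_equal(self.frame_index, other.frame_index)
            and np.allclose(self.red_xy, other.red_xy, equal_nan=True, atol=0)
            and np.allclose(self.green_xy, other.green_xy, equal_nan=True, atol=0)
            and self.frame_rate == other.frame_rate
        )


@dataclass
class EventLog:
    """Time-ordered behavioral events for one session."""

    table: pd.DataFrame  # columns time_s, kind, payload

    def __post_init__(self) -> None:
        t = self.table
        if list(t.columns) != ["time_s", "kind", "payload"]:
            t = t.reindex(columns=["time_s", "kind", "payload"])
        self.table = t.reset_index(drop=True)

    def times(self, kind: str) -> np.ndarray:
        cache = self.__dict__.setdefault("_times_cache", {})
        if kind not in cache:
            sel = self.table.loc[self.table["kind"] == kind, "time_s"]
            cache[kind] = sel.to_numpy(dtype=float)
        return cache[kind]

    def cue_onsets(self) -> pd.DataFrame:
        """Cue onsets as a frame: time_s, cue_type (DS|NS), offset_s."""
        rows = []
        for cue in ("DS", "NS"):
            on = self.times(f"{cue}_on")
            off = self.times(f"{cue}_off")
            for t in on:
                later = off[off > t]
                rows.append(
                    {
                        "time_s": t,
                        "cue_type": cue,
                        "offset_s": later[0] if later.size else np.nan,
                    }
                )
        frame = pd.DataFrame(rows, columns=["time_s", "cue_type", "offset_s"])
        return frame.sort_values("time_s", kind="stable").reset_index(drop=True)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EventLog):
            return NotImplemented
        a, b = self.table, other.table
        if len(a) != len(b):
            return False
        return bool(
            np.allclose(a["time_s"], b["time_s"])
            and (a["kind"].to_numpy() == b["kind"].to_numpy()).all()
            and (a["payload"].fillna("").to_numpy() == b["payload"].fillna("").to_numpy()).all()
        )


@dataclass
class SpikeTrain:
    """Spike timestamps (s, strictly increasing) of one neuron."""

    neuron_id: str
    spike_times: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float).ravel()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpikeTrain):
            return NotImplemented
        return (
            self.neuron_id == other.neuron_id
            and self.subject_id == other.subject_id
            and np.array_equal(self.spike_times, other.spike_times)
        )


@dataclass
class SessionManifest:
    frame_rate_hz: float
    duration_s: float
    arena_mm: tuple[float, float]
    lever_xy_mm: tuple[float, float]
    receptacle_xy_mm: tuple[float, float]
    subject_id: str = "subject"
    session_id: str = "session"
    infusion_time_s: Optional[float] = None
    infusion_condition: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "frame_rate_hz": self.frame_rate_hz,
            "duration_s": self.duration_s,
            "arena_mm": list(self.arena_mm),
            "lever_xy_mm": list(self.lever_xy_mm),
            "receptacle_xy_mm": list(self.receptacle_xy_mm),
            "subject_id": self.subject_id,
            "session_id": self.session_id,
            "infusion_time_s": self.infusion_time_s,
            "infusion_condition": self.infusion_condition,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SessionManifest":
        return cls(
            frame_rate_hz=float(d["frame_rate_hz"]),
            duration_s=float(d["duration_s"]),
            arena_mm=tuple(d["arena_mm"]),
            lever_xy_mm=tuple(d["lever_xy_mm"]),
            receptacle_xy_mm=tuple(d["receptacle_xy_mm"]),
            subject_id=str(d.get("subject_id", "subject")),
            session_id=str(d.get("session_id", "session")),
            infusion_time_s=d.get("infusion_time_s"),
            infusion_condition=d.get("infusion_condition"),
        )


@dataclass
class SessionBundle:
    tracking: TrackingSeries
    events: EventLog
    neurons: list[SpikeTrain]
    manifest: SessionManifest

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SessionBundle):
            return NotImplemented
        return (
            self.tracking == other.tracking
            and self.events == other.events
            and self.neurons == other.neurons
            and self.manifest.to_dict() == other.manifest.to_dict()
        )


# ---------------------------------------------------------------------------
# validation

def _inside_arena(xy: Sequence[float], arena: Sequence[float]) -> bool:
    return 0.0 <= xy[0] <= arena[0] and 0.0 <= xy[1] <= arena[1]


def validate_session(bundle: SessionBundle) -> list[str]:
    """Check every structural invariant; return a list of violations.

    Total: never raises on well-formed in-memory content.  An empty list
    means the bundle is valid.
    """
    out: list[str] = []
    man = bundle.manifest
    tr = bundle.tracking

    if man.frame_rate_hz <= 0:
        out.append("manifest: frame_rate_hz must be positive")
    if man.duration_s <= 0:
        out.append("manifest: duration_s must be positive")
    if not _inside_arena(man.lever_xy_mm, man.arena_mm):
        out.append("manifest: lever_xy_mm outside arena")
    if not _inside_arena(man.receptacle_xy_mm, man.arena_mm):
        out.append("manifest: receptacle_xy_mm outside arena")

    if tr.n_frames:
        if np.any(np.diff(tr.frame_index) <= 0):
            out.append("tracking: frame_index not strictly increasing")
        for name, arr in (("red", tr.red_xy), ("green", tr.green_xy)):
            bad = np.isinf(arr).any(axis=1)
            for i in np.flatnonzero(bad):
                out.append(f"tracking: non-finite {name} coordinate at frame index {i}")
    if tr.frame_rate != man.frame_rate_hz:
        out.append("tracking: frame_rate differs from manifest frame_rate_hz")

    ev = bundle.events.table
    times = ev["time_s"].to_numpy(dtype=float)
    if times.size and np.any(np.diff(times) < 0):
        out.append("events: times not nondecreasing")
    unknown = set(ev["kind"]) - EVENT_KINDS
    for k in sorted(unknown):
        out.append(f"events: unknown kind '{k}'")
    if times.size and (times.min() < 0 or times.max() > man.duration_s):
        out.append("events: event time outside session span")
    for cue in ("DS", "NS"):
        on = np.sort(bundle.events.times(f"{cue}_on"))
        off = np.sort(bundle.events.times(f"{cue}_off"))
        for t in on:
            later = off[off > t]
            if not later.size:
                out.append(f"events: {cue}_on at {t:.6f} s has no matching {cue}_off")
            elif later[0] - t > CUE_MAX_LENGTH_S + 1e-9:
                out.append(
                    f"events: {cue}_on at {t:.6f} s has offset more than "
                    f"{CUE_MAX_LENGTH_S:g} s later"
                )

    for tr_n in bundle.neurons:
        st = tr_n.spike_times
        if st.size and np.any(np.diff(st) <= 0):
            out.append(f"spikes: neuron {tr_n.neuron_id} times not strictly increasing")
        if st.size and (st.min() < 0 or st.max() > man.duration_s):
            out.append(f"spikes: neuron {tr_n.neuron_id} time outside session span")
    return out


# ---------------------------------------------------------------------------
# read / write

_FLOAT_FMT = "%.6f"


def write_session(bundle: SessionBundle, dest) -> dict[str, str]:
    """Write a validated bundle to ``dest``; returns {name: path} of files written."""
    violations = validate_session(bundle)
    if violations:
        raise SessionValidationError("; ".join(violations))
    dest = Path(dest)
    dest.mkdir(parents=True, exist_ok=True)

    tr = bundle.tracking
    tracking = pd.DataFrame(
        {
            "frame": tr.frame_index,
            "time_s": tr.time,
            "red_x_mm": tr.red_xy[:, 0],
            "red_y_mm": tr.red_xy[:, 1],
            "green_x_mm": tr.green_xy[:, 0],
            "green_y_mm": tr.green_xy[:, 1],
        }
    )
    paths = {
        "tracking.csv": dest / "tracking.csv",
        "events.csv": dest / "events.csv",
        "spikes.csv": dest / "spikes.csv",
        "manifest.json": dest / "manifest.json",
    }
    tracking.to_csv(paths["tracking.csv"], index=False, float_format=_FLOAT_FMT)
    bundle.events.table.to_csv(paths["events.csv"], index=False, float_format=_FLOAT_FMT)
    spikes = pd.DataFrame(
        {
            "neuron_id": np.concatenate(
                [[n.neuron_id] * len(n.spike_times) for n in bundle.neurons]
                or [np.array([], dtype=object)]
            ),
            "time_s": np.concatenate(
                [n.spike_times for n in bundle.neurons] or [np.array([])]
            ),
        }
    )
    spikes.to_csv(paths["spikes.csv"], index=False, float_format=_FLOAT_FMT)
    man = bundle.manifest.to_dict()
    man["neuron_subjects"] = {n.neuron_id: n.subject_id for n in bundle.neurons}
    man["neuron_order"] = [n.neuron_id for n in bundle.neurons]
    paths["manifest.json"].write_text(json.dumps(man, indent=2))
    return {k: str(v) for k, v in paths.items()}


def _read_csv(path: Path, **kw) -> pd.DataFrame:
    if not path.exists():
        raise SessionLoadError(f"missing file: {path.name}")
    try:
        return pd.read_csv(path, **kw)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise SessionLoadError(f"cannot parse {path.name}: {exc}") from exc


def load_session(root) -> SessionBundle:
    """Load and validate a session bundle from a directory.

    Missing-LED frames are preserved as NaN, not dropped.  Raises
    :class:`SessionLoadError` for missing/malformed files and
    :class:`SessionValidationError` if the loaded bundle violates invariants.
    """
    root = Path(root)
    man_path = root / "manifest.json"
    if not man_path.exists():
        raise SessionLoadError("missing file: manifest.json")
    raw = json.loads(man_path.read_text())
    manifest = SessionManifest.from_dict(raw)

    tracking_df = _read_csv(root / "tracking.csv")
    for col in ("frame", "red_x_mm", "red_y_mm", "green_x_mm", "green_y_mm"):
        if col not in tracking_df.columns:
            raise SessionLoadError(f"tracking.csv lacks column {col}")
    tracking = TrackingSeries(
        frame_index=tracking_df["frame"].to_numpy(dtype=int),
        red_xy=tracking_df[["red_x_mm", "red_y_mm"]].to_numpy(dtype=float),
        green_xy=tracking_df[["green_x_mm", "green_y_mm"]].to_numpy(dtype=float),
        frame_rate=manifest.frame_rate_hz,
    )

    events_df = _read_csv(root / "events.csv", dtype={"payload": str})
    for col in ("time_s", "kind"):
        if col not in events_df.columns:
            raise SessionLoadError(f"events.csv lacks column {col}")
    if "payload" not in events_df.columns:
        events_df["payload"] = ""
    events = EventLog(events_df)

    spikes_df = _read_csv(root / "spikes.csv", dtype={"neuron_id": str})
    subjects = raw.get("neuron_subjects", {})
    order = raw.get("neuron_order")
    if order is None:
        order = list(dict.fromkeys(spikes_df["neuron_id"])) if len(spikes_df) else []
    neurons = []
    grouped = (
        {k: v["time_s"].to_numpy(dtype=float) for k, v in spikes_df.groupby("neuron_id")}
        if len(spikes_df)
        else {}
    )
    for nid in order:
        neurons.append(
            SpikeTrain(
                neuron_id=str(nid),
                spike_times=np.sort(grouped.get(str(nid), np.array([]))),
                subject_id=str(subjects.get(str(nid), manifest.subject_id)),
            )
        )

    bundle = SessionBundle(tracking=tracking, events=events, neurons=neurons, manifest=manifest)
    violations = validate_session(bundle)
    if violations:
        raise SessionValidationError("; ".join(violations))
    return bundle
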