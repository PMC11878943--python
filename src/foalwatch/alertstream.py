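"""Parturition decision layer for continuous video-stream monitoring.

A deployed detector classifies one frame per second as MP (parturition) or
MNP (non-parturition).  This module turns those per-second labels into a
single alert decision per video, using either the first MP frame
(``first_detection``) or a 60-second sliding window that fires when strictly
more than a fraction θ of its frames are MP (``windowed``), and scores a set
of such decisions against annotated onset times by accuracy, mean delay and
maximum delay.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

MP, MNP = "MP", "MNP"

#: Window fractions evaluated for the sliding-window rule.
SWEEP_THETAS = (0.65, 0.70, 0.75, 0.80, 0.85, 0.90, 0.95)


@dataclass(frozen=True)
class FrameEntry:
    t: int
    label: str
    conf: float


@dataclass
class FrameLabelStream:
    """One label per second, timestamps strictly increasing by 1 s."""

    entries: list[FrameEntry]

    def __post_init__(self):
        for prev, cur in zip(self.entries, self.entries[1:]):
            if cur.t != prev.t + 1:
                raise ValueError(
                    f"timestamps must increase by 1 s, got {prev.t} -> {cur.t}"
                )
        for e in self.entries:
            if e.label not in (MP, MNP):
                raise ValueError(f"unknown label {e.label!r} at t={e.t}")

    def __len__(self) -> int:
        return len(self.entries)

    def labels(self) -> list[str]:
        return [e.label for e in self.entries]


@dataclass(frozen=True)
class AlertRule:
    window_s: int = 60
    theta: float = 0.75
    mode: str = "windowed"  # or "first_detection"

    def __post_init__(self):
        if self.mode not in ("windowed", "first_detection"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0.0 < self.theta < 1.0:
            raise ValueError("theta must lie strictly in (0, 1)")
        if self.window_s < 1:
            raise ValueError("window_s must be >= 1")

    @property
    def needed(self) -> int:
        """Minimum MP count for 'strictly more than theta of the window'."""
        import math

        return math.floor(self.theta * self.window_s) + 1


@dataclass(frozen=True)
class AlertEvent:
    reported_start_s: int
    issue_time_s: int
    rule: AlertRule


@dataclass
class AlertMetrics:
    accuracy: float  # percent of videos decided correctly
    mean_delay_s: float | None
    max_delay_s: float | None
    n_videos: int
    n_alerted: int


def best_label_per_frame(frame_detections: Sequence) -> tuple[str, float]:
    """Reduce a frame's detections to the single highest-confidence label.

    ``frame_detections`` is a sequence of objects with ``label`` and ``score``
    attributes (or ``(label, score)`` pairs).  An empty frame carries no
    evidence of parturition and is labelled MNP with confidence 0.  A
    confidence tie breaks toward MP: for an alerting system a missed
    parturition is costlier than a spurious window vote.
    """
    best: tuple[str, float] | None = None
    for det in frame_detections:
        label, score = (det.label, det.score) if hasattr(det, "label") else det
        if (
            best is None
            or score > best[1]
            or (score == best[1] and label == MP and best[0] != MP)
        ):
            best = (label, score)
    return best if best is not None else (MNP, 0.0)


def detect_parturition(stream: FrameLabelStream, rule: AlertRule) -> AlertEvent | None:
    """Scan a stream with an alert rule; return the first firing, if any."""
    labels = stream.labels()
    if rule.mode == "first_detection":
        for e in stream.entries:
            if e.label == MP:
                return AlertEvent(e.t, e.t, rule)
        return None
    W = rule.window_s
    if len(labels) < W:
        raise ValueError(f"stream length {len(labels)} shorter than window {W}")
    t0 = stream.entries[0].t
    flags = [1 if lb == MP else 0 for lb in labels]
    count = sum(flags[:W])
    for w in range(len(labels) - W + 1):
        if w > 0:
            count += flags[w + W - 1] - flags[w - 1]
        if count >= rule.needed:
            return AlertEvent(t0 + w, t0 + w + W - 1, rule)
    return None


def evaluate_alerts(
    events: Sequence[AlertEvent | None],
    onsets: Sequence[float | None],
    rule: AlertRule | None = None,
) -> AlertMetrics:
    """Score per-video alert decisions against annotated onsets.

    A video is decided correctly iff an alert fired and an onset exists, or
    neither.  Delay = issue time − onset, over videos that alerted and have
    an onset; it may be negative when window evidence precedes the
    annotation.
    """
    if len(events) != len(onsets):
        raise ValueError("one event slot and one onset slot per video required")
    correct = sum(
        1 for ev, on in zip(events, onsets) if (ev is not None) == (on is not None)
    )
    delays = [
        ev.issue_time_s - on for ev, on in zip(events, onsets)
        if ev is not None and on is not None
    ]
    return AlertMetrics(
        accuracy=100.0 * correct / len(events) if events else 100.0,
        mean_delay_s=sum(delays) / len(delays) if delays else None,
        max_delay_s=max(delays) if delays else None,
        n_videos=len(events),
        n_alerted=sum(ev is not None for ev in events),
    )


def threshold_sweep(
    streams: Sequence[FrameLabelStream],
    onsets: Sequence[float | None],
    thetas: Iterable[float] = SWEEP_THETAS,
    window_s: int = 60,
    include_first_detection: bool = True,
) -> dict[str, AlertMetrics]:
    """Evaluate every alert rule on every stream; one metrics row per rule."""
    if not streams:
        raise ValueError("at least one stream required")
    rules: list[AlertRule] = []
    if include_first_detection:
        rules.append(AlertRule(window_s=window_s, mode="first_detection"))
    rules.extend(AlertRule(window_s=window_s, theta=th) for th in thetas)
    table: dict[str, AlertMetrics] = {}
    for rule in rules:
        events = [detect_parturition(s, rule) for s in streams]
        key = (
            "first_detection"
            if rule.mode == "first_detection"
            else f"theta={rule.theta:.2f}"
        )
        table[key] = evaluate_alerts(events, onsets, rule)
    return table


# -- JSONL I/O ----------------------------------------------------------

def read_stream(path: str | Path) -> FrameLabelStream:
    entries = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            d = json.loads(line)
            entries.append(FrameEntry(int(d["t"]), d["label"], float(d["conf"])))
    return FrameLabelStream(entries)


def write_stream(stream: FrameLabelStream, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for e in stream.entries:
            fh.write(json.dumps({"t": e.t, "label": e.label, "conf": e.conf}) + "\n")
    return path
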