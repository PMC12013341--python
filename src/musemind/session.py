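"""Session timeline: a short resting baseline followed by counterbalanced
music / no-music mindfulness sections.

The default layout mirrors a single guided session: a 4-minute baseline
reading, then two 15-minute sections (one with live music, one without),
whose order is counterbalanced across sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

SECTION_LABELS = ("music", "no_music")


@dataclass(frozen=True)
class Section:
    """A labelled contiguous span of the session, in seconds from record start."""

    label: str
    start: float
    dur: float = 900.0

    def __post_init__(self) -> None:
        if self.label not in SECTION_LABELS:
            raise ValueError(f"section label must be one of {SECTION_LABELS}, got {self.label!r}")
        if self.dur <= 0:
            raise ValueError("section duration must be positive")

    @property
    def end(self) -> float:
        return self.start + self.dur


@dataclass(frozen=True)
class SessionTimeline:
    """Ordered layout of one recording: baseline then music/no-music sections.

    Invariants: the baseline precedes every section, sections do not overlap,
    and all durations are positive.
    """

    baseline_start: float = 0.0
    baseline_dur: float = 240.0
    sections: tuple[Section, ...] = field(default_factory=tuple)
    counterbalance_order: str = "music_first"

    def __post_init__(self) -> None:
        if self.baseline_dur <= 0:
            raise ValueError("baseline duration must be positive")
        baseline_end = self.baseline_start + self.baseline_dur
        prev_end = baseline_end
        for sec in self.sections:
            if sec.start < baseline_end:
                raise ValueError("baseline must precede all sections")
            if sec.start < prev_end:
                raise ValueError("sections must be non-overlapping and ordered")
            prev_end = sec.end

    @property
    def baseline_end(self) -> float:
        return self.baseline_start + self.baseline_dur

    @property
    def total_dur(self) -> float:
        """Duration from time 0 to the end of the last labelled span."""
        if self.sections:
            return self.sections[-1].end
        return self.baseline_end

    def windows(self) -> dict[str, tuple[float, float]]:
        """Labelled (start, end) spans: baseline plus each section."""
        out = {"baseline": (self.baseline_start, self.baseline_end)}
        for sec in self.sections:
            out[sec.label] = (sec.start, sec.end)
        return out


def default_timeline(
    order: str = "music_first",
    baseline_dur: float = 240.0,
    section_dur: float = 900.0,
    inter_gap: float = 60.0,
) -> SessionTimeline:
    """Standard session: baseline, then the two sections with a short gap.

    ``order`` is ``"music_first"`` or ``"no_music_first"`` (the study
    counterbalanced this across sessions).
    """
    if order == "music_first":
        labels = ("music", "no_music")
    elif order == "no_music_first":
        labels = ("no_music", "music")
    else:
        raise ValueError("order must be 'music_first' or 'no_music_first'")
    s0 = baseline_dur + inter_gap
    sections = (
        Section(labels[0], s0, section_dur),
        Section(labels[1], s0 + section_dur + inter_gap, section_dur),
    )
    return SessionTimeline(0.0, baseline_dur, sections, order)
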