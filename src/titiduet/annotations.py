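"""Syllable-level annotation tracks (Audacity label-track TSV).

Each event is one syllable with its phrase context and the sex of the caller.
Labels follow the syntax ``sex:phrase:syllable`` (e.g. ``m:pant:pant`` or
``f:bellow-cre:bellow``); the phrase field may carry a ``-cre``/``-dec``
suffix marking the crescendo or decrescendo sub-phase of a bellow series.
Times are written with 6-decimal precision, matching Audacity's export.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

__all__ = ["Event", "AnnotationTrack", "read_labels", "write_labels"]


class LabelFormatError(ValueError):
    """Raised for malformed label files; carries the offending line number."""


@dataclass(frozen=True, order=True)
class Event:
    onset: float
    offset: float
    sex: str          # "m" | "f" (or "j" for an optional juvenile voice)
    phrase: str       # pant, bellow, bellow-cre, pump, arch, whinny, ...
    syllable: str

    def __post_init__(self) -> None:
        if not self.offset > self.onset:
            raise ValueError(f"offset {self.offset} must exceed onset {self.onset}")
        if self.onset < 0:
            raise ValueError("onset must be non-negative")

    @property
    def phrase_base(self) -> str:
        """Phrase type with any crescendo/decrescendo suffix stripped."""
        return self.phrase.split("-")[0]

    @property
    def subphase(self) -> str | None:
        parts = self.phrase.split("-", 1)
        return parts[1] if len(parts) == 2 else None

    @property
    def label(self) -> str:
        return f"{self.sex}:{self.phrase}:{self.syllable}"


class AnnotationTrack:
    """An ordered collection of labeled syllable events."""

    def __init__(self, events: Iterable[Event]):
        self.events: list[Event] = sorted(events, key=lambda e: (e.onset, e.offset))

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[Event]:
        return iter(self.events)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, AnnotationTrack) and self.events == other.events

    def select(self, sex: str | None = None, phrase_base: str | None = None) -> "AnnotationTrack":
        ev = [e for e in self.events
              if (sex is None or e.sex == sex)
              and (phrase_base is None or e.phrase_base == phrase_base)]
        return AnnotationTrack(ev)

    def phrase_groups(self, sex: str | None = None,
                      phrase_base: str | None = None) -> list[list[Event]]:
        """Group consecutive events of one voice that share a phrase run.

        Events are first partitioned into per-voice, per-phrase-label
        streams (the two voices overlap in time, so global adjacency would
        fragment concurrent phrases), then each stream is split wherever a
        gap larger than ``1.2 s`` separates consecutive onsets — distinct
        phrases of the same type in successive sequences; within-phrase
        onset intervals never exceed ~0.8 s at the call rates of these taxa.
        """
        streams: dict[tuple[str, str], list[Event]] = {}
        for e in self.select(sex=sex, phrase_base=phrase_base):
            streams.setdefault((e.sex, e.phrase), []).append(e)
        groups: list[list[Event]] = []
        for stream in streams.values():
            current = [stream[0]]
            for e in stream[1:]:
                if e.onset - current[-1].onset < 1.2:
                    current.append(e)
                else:
                    groups.append(current)
                    current = [e]
            groups.append(current)
        groups.sort(key=lambda g: g[0].onset)
        return groups

    @property
    def duration(self) -> float:
        return self.events[-1].offset if self.events else 0.0


def read_labels(path: str | Path) -> AnnotationTrack:
    """Parse an Audacity label-track TSV (start, end, label)."""
    path = Path(path)
    events = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise LabelFormatError(f"{path}:{lineno}: expected 3 tab-separated "
                                       f"columns, got {len(parts)}")
            try:
                onset, offset = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise LabelFormatError(f"{path}:{lineno}: non-numeric time") from exc
            label = parts[2].split(":")
            if len(label) != 3:
                raise LabelFormatError(f"{path}:{lineno}: label must be "
                                       f"'sex:phrase:syllable', got {parts[2]!r}")
            try:
                events.append(Event(onset, offset, *label))
            except ValueError as exc:
                raise LabelFormatError(f"{path}:{lineno}: {exc}") from exc
    return AnnotationTrack(events)


def write_labels(track: AnnotationTrack, path: str | Path) -> None:
    with open(Path(path), "w") as fh:
        for e in track:
            fh.write(f"{e.onset:.6f}\t{e.offset:.6f}\t{e.label}\n")
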