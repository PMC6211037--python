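"""Sequence segmentation and call-rate statistics.

A "male duet sequence" runs from the first male pant syllable at the onset
of one sequence to the first male pant syllable of the next, so a track
with k male pant-phrase starts yields k-1 bounded sequences (the trailing
unbounded interval is discarded).  Call rate within a phrase is the number
of syllables minus one divided by the span from first to last onset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .annotations import AnnotationTrack, Event
from .audio import AudioSignal
from .spectral import dominant_frequency, mean_power_spectrum

__all__ = [
    "DuetSequence",
    "FeatureRow",
    "segment_sequences",
    "call_rate",
    "phrase_rates",
    "crescendo_decrescendo_rates",
    "assemble_feature_table",
]

log = logging.getLogger(__name__)

#: "rhythmic" phrases in the donacophilus group are the analogue of the
#: moloch pump climax and are treated as pump phrases.
PHRASE_ALIASES = {"pump": ("pump", "rhythmic")}


@dataclass(frozen=True)
class DuetSequence:
    start: float
    end: float
    events: tuple[Event, ...]

    @property
    def duration(self) -> float:
        return self.end - self.start

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError("sequence end must exceed start")


@dataclass(frozen=True)
class FeatureRow:
    """One duet's predictors: the sampling unit of the whole analysis."""

    group: str
    species: str
    lineage: str
    dominant_frequency: float   # Hz
    sequence_duration: float    # s, mean over the duet's sequences
    pant_rate: float            # calls/s, mean over the duet's pant phrases


def segment_sequences(track: AnnotationTrack) -> list[DuetSequence]:
    """Split a duet at successive first-male-pant-phrase onsets."""
    groups = track.phrase_groups(sex="m", phrase_base="pant")
    markers = [g[0].onset for g in groups]
    if len(markers) < 2:
        raise ValueError("need at least two male pant-phrase onsets to segment")
    sequences = []
    for start, end in zip(markers[:-1], markers[1:]):
        ev = tuple(e for e in track if start <= e.onset < end)
        sequences.append(DuetSequence(start, end, ev))
    return sequences


def call_rate(onsets: list[float]) -> float:
    """(n - 1) / (last onset - first onset), in calls/s."""
    if len(onsets) < 2:
        raise ValueError("call rate needs at least two onsets")
    diffs = [b - a for a, b in zip(onsets[:-1], onsets[1:])]
    if any(d <= 0 for d in diffs):
        raise ValueError("onsets must be strictly increasing")
    return (len(onsets) - 1) / (onsets[-1] - onsets[0])


def phrase_rates(track: AnnotationTrack, phrase_type: str,
                 sex: str | None = None) -> list[float]:
    """One call rate per phrase of the requested type (both voices by default).

    Single-syllable phrases cannot carry a rate and are skipped with a
    logged warning; an empty result is allowed.
    """
    bases = PHRASE_ALIASES.get(phrase_type, (phrase_type,))
    rates = []
    n_skipped = 0
    for base in bases:
        for group in track.phrase_groups(sex=sex, phrase_base=base):
            if len(group) < 2:
                n_skipped += 1
                continue
            rates.append(call_rate([e.onset for e in group]))
    if n_skipped:
        log.warning("skipped %d single-syllable %s phrase(s)", n_skipped, phrase_type)
    if not rates:
        log.warning("no %s phrases with >=2 syllables found", phrase_type)
    return rates


def crescendo_decrescendo_rates(track: AnnotationTrack,
                                ) -> list[tuple[float, float]]:
    """Per-sequence (crescendo rate, decrescendo rate) of the bellow series.

    Requires bellow phrases annotated with the ``-cre``/``-dec`` sub-phase
    suffix; the paired differences feed the exact signed-rank test.
    """
    labelled = [e for e in track if e.phrase_base == "bellow" and e.subphase]
    if not labelled:
        raise ValueError(
            "no crescendo/decrescendo sub-phase labels found; bellow events "
            "must carry 'bellow-cre' / 'bellow-dec' phrase labels")
    pairs = []
    for seq in segment_sequences(track):
        seq_track = AnnotationTrack(seq.events)
        by_phase = {}
        for phase in ("cre", "dec"):
            groups = [g for g in seq_track.phrase_groups(phrase_base="bellow")
                      if g[0].subphase == phase and len(g) >= 2]
            if groups:
                by_phase[phase] = sum(
                    call_rate([e.onset for e in g]) for g in groups) / len(groups)
        if "cre" in by_phase and "dec" in by_phase:
            pairs.append((by_phase["cre"], by_phase["dec"]))
    return pairs


def assemble_feature_table(duets: list[tuple[AudioSignal, AnnotationTrack, dict]],
                           ) -> list[FeatureRow]:
    """One row per duet: dominant frequency, mean sequence duration, mean
    pant rate.

    The duet (one per family group) is the sampling unit; a duplicate group
    id is rejected as pseudoreplication, and a duet from which any feature
    cannot be computed is excluded with a log entry.
    """
    rows = []
    seen = set()
    for signal, track, meta in duets:
        group = meta["group"]
        if group in seen:
            raise ValueError(f"duplicate duet for group {group!r}: "
                             "only one duet per group is allowed")
        seen.add(group)
        try:
            dom = dominant_frequency(mean_power_spectrum(signal))
            seqs = segment_sequences(track)
            pants = phrase_rates(track, "pant")
            if not pants:
                raise ValueError("no measurable pant phrase")
            rows.append(FeatureRow(
                group=group, species=meta["species"], lineage=meta["lineage"],
                dominant_frequency=dom,
                sequence_duration=sum(s.duration for s in seqs) / len(seqs),
                pant_rate=sum(pants) / len(pants)))
        except ValueError as exc:
            log.warning("excluding duet %r: %s", group, exc)
    return rows
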