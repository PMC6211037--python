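"""Synthetic duet generator with lineage-specific grammars.

Field recordings of titi duets are not publicly deposited, so every
downstream stage of the pipeline is exercised on synthetic duets whose
acoustic and temporal statistics are controlled by per-species profiles.
The generator follows the hierarchical organization of the real calls:
syllables -> phrases (runs of paired syllables at a set rate) -> sequences
(one pass through the grammar, delimited by the first male pant onset) ->
a duet of several sequences with two overlapping voices.

Syllable acoustics are stylized, not perceptual: bellows are harmonic stacks
with slow FM, pants and terminal elements are band-limited noise bursts,
pumps are short high-rate bursts, arches and whinnies are tonal FM sweeps,
and hoots/moans are low narrowband tones.  This reproduces the broadband vs
narrowband split that separates the lineages without attempting voice
modeling.  Loud phrases (bellows, arches) sit 12 dB above soft phrases
(pants), mirroring the relative audibility of the two voices in the field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from scipy.signal import butter, sosfiltfilt
from scipy.signal.windows import tukey

from .annotations import AnnotationTrack, Event
from .audio import AudioSignal

__all__ = [
    "SyllableTemplate",
    "PhraseSpec",
    "SequenceGrammar",
    "SpeciesProfile",
    "GroundTruth",
    "render_syllable",
    "build_phrase",
    "synthesize_duet",
    "add_background",
    "profile_library",
    "load_profiles",
]

LINEAGES = ("donacophilus", "moloch", "torquatus", "oenanthe")

#: -12 dB gain of soft phrases relative to loud phrases
SOFT_GAIN = 10 ** (-12 / 20)
#: default female offset added to bellow carriers, Hz
FEMALE_BELLOW_OFFSET = 100.0


class AliasingError(ValueError):
    """Carrier content would exceed the Nyquist frequency."""


# ---------------------------------------------------------------- templates

@dataclass(frozen=True)
class SyllableTemplate:
    """One syllable class: spectral shape and duration."""

    name: str
    carrier: float          # Hz, center frequency
    bandwidth: float        # Hz; FM depth for tonal, noise band for noisy
    duration: float         # s
    contour: str = "flat"   # flat | rise | fall | arch
    harmonic_count: int = 1
    noisiness: float = 0.0  # 0 = pure tonal, 1 = pure noise
    amplitude: float = 1.0  # relative linear gain

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.carrier - self.bandwidth / 2 <= 0:
            raise ValueError("carrier - bandwidth/2 must be positive")
        if not 0 <= self.noisiness <= 1:
            raise ValueError("noisiness must be in [0, 1]")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.contour not in ("flat", "rise", "fall", "arch"):
            raise ValueError(f"unknown contour {self.contour!r}")
        if self.harmonic_count < 1:
            raise ValueError("harmonic_count must be >= 1")


@dataclass(frozen=True)
class PhraseSpec:
    """A run of similar syllables produced at a set rate by one voice."""

    phrase: str                    # annotation label, e.g. "pant", "bellow-cre"
    syllable: SyllableTemplate
    count_range: tuple[int, int]   # inclusive
    rate: float                    # calls/s (onset-to-onset)
    rate_trend: float = 1.0        # <1: slow start (crescendo), >1: fast start
    voice: str = "m"               # m | f
    paired: bool = False           # inhale-exhale alternation of variants
    jitter_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.count_range[0] < 1 or self.count_range[1] < self.count_range[0]:
            raise ValueError("count_range must satisfy 1 <= min <= max")
        if self.rate <= 0:
            raise ValueError("rate must be positive")


@dataclass(frozen=True)
class SequenceGrammar:
    """Ordered phrase lists per voice plus the overlap rule.

    ``overlap`` maps a female phrase index to the male phrase index whose
    start it shares; female phrases not in the map follow the previous
    female phrase.  ``marker`` names, per voice, the phrase whose first
    onset defines sequence start (the male marker drives segmentation).
    """

    male: tuple[PhraseSpec, ...]
    female: tuple[PhraseSpec, ...]
    overlap: dict[int, int] = field(default_factory=dict)
    period: float = 10.0           # s, target sequence duration
    marker: dict[str, int] = field(default_factory=lambda: {"m": 0, "f": 0})
    phrase_gap: float = 0.25       # s between consecutive same-voice phrases

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be positive")
        for voice, phrases in (("m", self.male), ("f", self.female)):
            if voice not in self.marker or not 0 <= self.marker[voice] < len(phrases):
                raise ValueError(f"exactly one valid marker required for voice {voice}")


@dataclass(frozen=True)
class SpeciesProfile:
    species: str
    lineage: str                    # published (taxonomic) lineage
    acoustic_lineage: str           # lineage the duet pattern conforms to
    grammar: SequenceGrammar
    dominant_frequency_target: float
    pant_rate_target: float
    sequence_duration_target: float
    sex_offset: float = FEMALE_BELLOW_OFFSET
    bellows_per_sequence_range: tuple[int, int] = (1, 1)
    pump_present: bool = False
    jitter: float = 0.05            # CV for onset intervals and the period

    def __post_init__(self) -> None:
        if self.lineage not in LINEAGES or self.acoustic_lineage not in LINEAGES:
            raise ValueError(f"lineage must be one of {LINEAGES}")
        for target in (self.dominant_frequency_target, self.pant_rate_target,
                       self.sequence_duration_target):
            if target <= 0:
                raise ValueError("profile targets must be positive")


@dataclass
class GroundTruth:
    """What was actually rendered: the oracle for round-trip tests."""

    track: AnnotationTrack
    sequence_durations: list[float]          # successive male-marker gaps
    phrase_rates: list[tuple[str, str, float]]  # (voice, phrase, realized rate)
    inventory: dict[str, dict[str, int]]     # voice -> syllable -> count


# ---------------------------------------------------------------- rendering

def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _contour_deviation(contour: str, bandwidth: float, u: np.ndarray) -> np.ndarray:
    """Instantaneous frequency deviation from the carrier, in Hz.

    ``flat`` applies a slow (3 Hz) vibrato of depth bandwidth/2, giving the
    bellow its gentle FM without moving the spectral peak off-carrier.
    """
    half = bandwidth / 2.0
    if contour == "flat":
        return half * np.sin(2 * np.pi * 3.0 * u)
    if contour == "rise":
        return -half + bandwidth * u
    if contour == "fall":
        return half - bandwidth * u
    # arch: up then back down
    return -half + bandwidth * np.sin(np.pi * u)


def render_syllable(template: SyllableTemplate, rate_hz: int,
                    seed: int | np.random.Generator = 0) -> AudioSignal:
    """Render one syllable as a tonal/noise mixture with a tapered envelope."""
    nyquist = rate_hz / 2.0
    top = template.carrier * template.harmonic_count + template.bandwidth / 2.0
    if top >= nyquist:
        raise AliasingError(
            f"syllable {template.name!r}: content up to {top:.0f} Hz exceeds "
            f"Nyquist ({nyquist:.0f} Hz) at fs={rate_hz}")
    rng = _as_rng(seed)
    n = max(8, round(template.duration * rate_hz))
    u = np.arange(n) / n
    dt = 1.0 / rate_hz

    out = np.zeros(n)
    if template.noisiness < 1.0:
        freq = template.carrier + _contour_deviation(template.contour,
                                                     template.bandwidth, u)
        phase = 2 * np.pi * np.cumsum(freq) * dt
        tonal = np.zeros(n)
        for h in range(1, template.harmonic_count + 1):
            tonal += np.sin(h * phase + rng.uniform(0, 2 * np.pi)) / h
        tonal /= np.sqrt(np.mean(tonal**2))
        out += math.sqrt(1.0 - template.noisiness) * tonal
    else:
        rng.uniform(0, 2 * np.pi, template.harmonic_count)  # keep stream aligned
    if template.noisiness > 0.0:
        bw = max(template.bandwidth, 20.0)
        lo = max(1.0, template.carrier - bw / 2)
        hi = min(nyquist * 0.98, template.carrier + bw / 2)
        noise = rng.standard_normal(n)
        sos = butter(4, (lo, hi), btype="bandpass", fs=rate_hz, output="sos")
        noise = sosfiltfilt(sos, noise)
        noise /= np.sqrt(np.mean(noise**2))
        out += math.sqrt(template.noisiness) * noise

    out *= tukey(n, alpha=0.3)
    peak = np.max(np.abs(out))
    if peak > 0:
        out *= template.amplitude / peak
    return AudioSignal(out, rate_hz)


def _phrase_onsets(spec: PhraseSpec, count: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Onset times (s, relative to phrase start) for ``count`` syllables.

    The local rate ramps linearly from ``rate * trend`` to ``rate * (2 -
    trend)``, so the mean interval stays at 1/rate while trend < 1 makes the
    first half slower than the second (crescendo).  Multiplicative Gaussian
    jitter is truncated at 0.2 to keep onsets strictly increasing.
    """
    if count == 1:
        return np.zeros(1)
    steps = np.arange(count - 1)
    frac = steps / max(count - 2, 1)
    local_rate = spec.rate * (spec.rate_trend + (2.0 - 2.0 * spec.rate_trend) * frac)
    intervals = 1.0 / local_rate
    if spec.jitter_cv > 0:
        intervals = intervals * np.maximum(
            0.2, 1.0 + spec.jitter_cv * rng.standard_normal(count - 1))
    else:
        rng.standard_normal(count - 1)  # keep stream aligned across jitter settings
    return np.concatenate([[0.0], np.cumsum(intervals)])


def build_phrase(spec: PhraseSpec, rate_hz: int = 44100,
                 seed: int | np.random.Generator = 0,
                 ) -> tuple[AudioSignal, list[Event]]:
    """Render one phrase and its syllable annotations (phrase-relative times).

    Paired emission alternates an exhaled syllable with a slightly softer,
    lower inhaled variant at the same uniform onset spacing, so syllable
    counts and call rates count every syllable individually.
    """
    rng = _as_rng(seed)
    count = int(rng.integers(spec.count_range[0], spec.count_range[1] + 1))
    onsets = _phrase_onsets(spec, count, rng)
    inhale = replace(spec.syllable, carrier=spec.syllable.carrier * 0.98,
                     amplitude=spec.syllable.amplitude * 0.85)
    total = int(round((onsets[-1] + spec.syllable.duration * 1.5) * rate_hz))
    buf = np.zeros(total)
    events = []
    for i, onset in enumerate(onsets):
        template = inhale if (spec.paired and i % 2 == 1) else spec.syllable
        syl = render_syllable(template, rate_hz, rng)
        i0 = int(round(onset * rate_hz))
        buf[i0:i0 + syl.n_samples] += syl.samples
        events.append(Event(onset=float(onset),
                            offset=float(onset) + syl.duration,
                            sex=spec.voice, phrase=spec.phrase,
                            syllable=spec.syllable.name))
    return AudioSignal(buf, rate_hz), events


# ---------------------------------------------------------------- duets

def synthesize_duet(profile: SpeciesProfile, n_sequences: int,
                    rate_hz: int = 44100, seed: int | np.random.Generator = 0,
                    chorus: bool = False,
                    ) -> tuple[AudioSignal, GroundTruth]:
    """Render a two-voice duet of ``n_sequences`` bounded sequences.

    ``n_sequences + 1`` male marker onsets are laid down (the last one as a
    stub pant phrase), so segmentation on marker onsets recovers exactly
    ``n_sequences`` bounded sequences.  An optional juvenile chorus voice
    duplicates the female part shifted up by 50 Hz.
    """
    if n_sequences < 1:
        raise ValueError("n_sequences must be >= 1")
    rng = _as_rng(seed)
    g = profile.grammar

    # marker (sequence-start) times
    starts = [0.5]
    for _ in range(n_sequences):
        jit = max(0.5, 1.0 + profile.jitter * rng.standard_normal())
        starts.append(starts[-1] + g.period * jit)

    placements: list[tuple[float, PhraseSpec]] = []
    for k in range(n_sequences):
        t0 = starts[k]
        male_starts: list[float] = []
        cursor = t0
        for spec in g.male:
            male_starts.append(cursor)
            # provisional span to advance the cursor; realized span may differ
            span = (sum(spec.count_range) / 2 - 1) / spec.rate
            cursor += max(span, spec.syllable.duration) + g.phrase_gap
            placements.append((male_starts[-1], spec))
        f_cursor = t0 + 0.15
        for i, spec in enumerate(g.female):
            if i in g.overlap:
                f_start = male_starts[g.overlap[i]] + 0.1
            else:
                f_start = f_cursor
            span = (sum(spec.count_range) / 2 - 1) / spec.rate
            f_cursor = f_start + max(span, spec.syllable.duration) + g.phrase_gap
            placements.append((f_start, spec))
    # trailing stub: one male marker phrase to bound the final sequence
    stub = g.male[g.marker["m"]]
    placements.append((starts[-1], stub))

    total = int(round((starts[-1] + 2.0 * g.period) * rate_hz))
    buf = np.zeros(total)
    events: list[Event] = []
    rates: list[tuple[str, str, float]] = []
    inventory: dict[str, dict[str, int]] = {}
    for p_start, spec in placements:
        audio, ph_events = build_phrase(spec, rate_hz, rng)
        i0 = int(round(p_start * rate_hz))
        end = min(i0 + audio.n_samples, total)
        buf[i0:end] += audio.samples[: end - i0]
        for e in ph_events:
            events.append(Event(e.onset + p_start, e.offset + p_start,
                                e.sex, e.phrase, e.syllable))
            inv = inventory.setdefault(e.sex, {})
            inv[e.syllable] = inv.get(e.syllable, 0) + 1
        if len(ph_events) >= 2:
            span = ph_events[-1].onset - ph_events[0].onset
            rates.append((spec.voice, spec.phrase, (len(ph_events) - 1) / span))

    if chorus:
        juv = np.zeros(total)
        for p_start, spec in placements:
            if spec.voice != "f":
                continue
            shifted = replace(spec, voice="j", syllable=replace(
                spec.syllable, carrier=spec.syllable.carrier + 50.0,
                amplitude=spec.syllable.amplitude * 0.5))
            audio, ph_events = build_phrase(shifted, rate_hz, rng)
            i0 = int(round((p_start + 0.05) * rate_hz))
            end = min(i0 + audio.n_samples, total)
            juv[i0:end] += audio.samples[: end - i0]
            for e in ph_events:
                events.append(Event(e.onset + p_start + 0.05,
                                    e.offset + p_start + 0.05,
                                    "j", e.phrase, e.syllable))
                inv = inventory.setdefault("j", {})
                inv[e.syllable] = inv.get(e.syllable, 0) + 1
        buf += juv

    # trim trailing silence past the last rendered sample
    last = int(round((max(e.offset for e in events) + 0.2) * rate_hz))
    buf = buf[: min(last, total)]
    peak = np.max(np.abs(buf))
    if peak > 0:
        buf *= 0.9 / peak
    durations = list(np.diff(starts))
    return AudioSignal(buf, rate_hz), GroundTruth(
        track=AnnotationTrack(events), sequence_durations=durations,
        phrase_rates=rates, inventory=inventory)


def add_background(signal: AudioSignal, kind: str = "insect_band",
                   snr_db: float = 10.0,
                   seed: int | np.random.Generator = 0) -> AudioSignal:
    """Add noise at a target SNR: 6-7 kHz insect band or broadband.

    An infinite SNR is the no-noise sentinel and returns the signal
    unchanged.
    """
    if not np.isfinite(snr_db):
        if snr_db > 0:
            return signal
        raise ValueError("snr_db must be finite or +inf")
    rng = _as_rng(seed)
    noise = rng.standard_normal(signal.n_samples)
    if kind == "insect_band":
        if signal.rate <= 14000:
            raise ValueError("insect-band noise (6-7 kHz) needs fs > 14 kHz")
        sos = butter(6, (6000.0, 7000.0), btype="bandpass", fs=signal.rate,
                     output="sos")
        noise = sosfiltfilt(sos, noise)
    elif kind != "broadband":
        raise ValueError(f"kind must be insect_band|broadband, got {kind!r}")
    p_signal = np.mean(signal.samples**2)
    p_noise = np.mean(noise**2)
    noise *= np.sqrt(p_signal / (p_noise * 10 ** (snr_db / 10)))
    return signal.replace(signal.samples + noise)


# ---------------------------------------------------------------- profiles

def _syl(name, carrier, bw, dur, contour="flat", harmonics=1, noise=0.0, amp=1.0):
    return SyllableTemplate(name, carrier, bw, dur, contour, harmonics, noise, amp)


def _build_grammar(p: dict, jitter: float) -> SequenceGrammar:
    """Assemble a lineage-patterned grammar from per-species numbers."""
    f0 = p["dominant_frequency_hz"]
    off = p.get("sex_offset_hz", FEMALE_BELLOW_OFFSET)
    pant_rate = p["pant_rate_cps"]
    period = p["sequence_duration_s"]
    pattern = p["pattern"]

    pant = _syl("pant", min(f0, 1100.0), 600.0, 0.09, noise=1.0, amp=SOFT_GAIN)
    bell_m = _syl("bellow", f0, 24.0, 0.30, harmonics=5, noise=0.1)
    bell_f = _syl("bellow", f0 + off, 24.0, 0.30, harmonics=5, noise=0.1, amp=0.9)

    def P(phrase, syl, count, rate, voice, trend=1.0, paired=True):
        return PhraseSpec(phrase, syl, count, rate, trend, voice,
                          paired=paired, jitter_cv=jitter)

    if pattern == "moloch":
        b_lo, b_hi = p["bellows_range"]
        cre, dec = p["bellow_rate_cre_cps"], p["bellow_rate_dec_cps"]
        n_cre = (max(1, b_lo // 2), max(1, b_hi // 2))
        n_dec = (b_lo - n_cre[0], b_hi - n_cre[1])
        pump = _syl("pump", f0, 400.0, 0.07, noise=0.5, amp=0.5)
        male = (
            P("pant", pant, (9, 11), pant_rate, "m"),
            P("bellow-cre", bell_m, n_cre, cre, "m"),
            P("bellow-dec", bell_m, n_dec, dec, "m"),
            P("pump", pump, (4, 6), p["pump_rate_cps"], "m", paired=False),
        )
        female = (
            P("bellow-cre", bell_f, n_cre, cre, "f"),
            P("bellow-dec", bell_f, n_dec, dec, "f"),
            P("pant", pant, (9, 11), pant_rate, "f"),
            P("pump", pump, (4, 6), p["pump_rate_cps"], "f", paired=False),
        )
        # female bellows overlap the male pant phrase and vice versa
        overlap = {0: 0, 2: 1, 3: 3}
    elif pattern == "donacophilus":
        hoot = _syl("hoot", max(f0 * 0.55, 250.0), 20.0, 0.15, harmonics=3, amp=0.5)
        arch = _syl("arch", f0, 180.0, 0.22, contour="arch", harmonics=2, amp=0.85)
        rhythmic = _syl("rhythmic", f0, 350.0, 0.08, noise=0.6, amp=0.5)
        te = _syl("te", min(f0 * 1.2, 1600.0), 500.0, 0.08, noise=1.0, amp=SOFT_GAIN)
        male = (
            P("pant", pant, (7, 9), pant_rate, "m"),
            P("bellow", bell_m, (2, 4), 2.5, "m"),
            P("arch", arch, (2, 3), 2.0, "m"),
            P("rhythmic", rhythmic, (3, 4), p["rhythmic_rate_cps"], "m", paired=False),
        )
        female = (
            P("hoot", hoot, (2, 3), 2.0, "f"),
            P("bellow", bell_f, (2, 4), 2.5, "f"),
            P("pant", pant, (7, 9), pant_rate, "f"),
            P("te", te, (2, 3), pant_rate, "f"),
        )
        # female-dominated section (her bellows over his pants) precedes the
        # male-dominated section (his bellows/arches over her pants)
        overlap = {0: 0, 1: 0, 2: 1}
    elif pattern == "torquatus":
        pantA = _syl("pant", f0, 300.0, 0.20, harmonics=2, noise=0.5, amp=SOFT_GAIN)
        syl_b = _syl("noisy", f0, 150.0, 0.30, harmonics=3, noise=0.4)
        syl_c = _syl("c", f0 * 1.1, 200.0, 0.20, harmonics=2, noise=0.3, amp=0.7)
        arch = _syl("arch", f0, 160.0, 0.25, contour="arch", harmonics=2, amp=0.8)
        male = (
            P("pant", pantA, (4, 6), pant_rate, "m"),
            P("phraseB", syl_b, (2, 4), p["phraseB_rate_cps"], "m"),
            P("phraseC", syl_c, (2, 4), p["phraseC_rate_cps"], "m"),
        )
        female = (
            P("arch", arch, (3, 4), 1.8, "f"),
            P("pant", pantA, (4, 6), pant_rate, "f"),
        )
        overlap = {0: 0, 1: 1}
    elif pattern == "oenanthe":
        iiyep = _syl("iii-yep", f0, 60.0, 0.18, contour="rise", amp=1.0)
        whinny = _syl("whinny", f0, 250.0, 0.20, contour="arch", amp=0.8)
        chuck = _syl("chuck", min(f0, 1300.0), 500.0, 0.06, noise=0.8, amp=0.4)
        hoot = _syl("hoot", f0 * 0.55, 20.0, 0.15, harmonics=2, amp=0.5)
        whine = _syl("whine", 5000.0, 800.0, 0.25, contour="fall", amp=0.3)
        bell = _syl("bellow", f0 * 0.75, 24.0, 0.30, harmonics=4, noise=0.1, amp=0.9)
        male = (
            P("pant", pant, (10, 12), pant_rate, "m"),
            P("bellow", bell, (4, 6), 2.3, "m"),
            P("iii-yep", iiyep, (5, 7), 2.2, "m"),
            P("whinny", whinny, (6, 8), 2.4, "m", trend=0.85),
            P("chuck", chuck, (4, 6), 3.5, "m", paired=False),
            P("hoot", hoot, (2, 3), 2.0, "m"),
        )
        female = (
            P("iii-yep", iiyep, (5, 7), 2.2, "f"),
            P("whinny", whinny, (6, 8), 2.4, "f", trend=0.85),
            P("whine", whine, (2, 3), 1.5, "f", paired=False),
            P("pant", pant, (10, 12), pant_rate, "f"),
            P("hoot", hoot, (2, 3), 2.0, "f"),
        )
        overlap = {0: 0, 3: 1}
    else:
        raise ValueError(f"unknown duet pattern {pattern!r}")

    return SequenceGrammar(male=male, female=female, overlap=overlap,
                           period=period, marker={"m": 0, "f": _marker(female)})


def _marker(female: tuple[PhraseSpec, ...]) -> int:
    for i, spec in enumerate(female):
        if spec.phrase == "pant":
            return i
    return 0


def load_profiles(path: str | Path | None = None) -> dict[str, SpeciesProfile]:
    """Load the species profiles shipped with the package (or a user YAML)."""
    if path is None:
        text = resources.files("titiduet").joinpath("data/profiles.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    profiles = {}
    for name, p in raw["species"].items():
        jitter = p.get("jitter_cv", 0.05)
        grammar = _build_grammar(p, jitter)
        profiles[name] = SpeciesProfile(
            species=name,
            lineage=p["lineage"],
            acoustic_lineage=p.get("acoustic_lineage", p["lineage"]),
            grammar=grammar,
            dominant_frequency_target=p["dominant_frequency_hz"],
            pant_rate_target=p["pant_rate_cps"],
            sequence_duration_target=p["sequence_duration_s"],
            sex_offset=p.get("sex_offset_hz", FEMALE_BELLOW_OFFSET),
            bellows_per_sequence_range=tuple(p.get("bellows_range", (1, 1))),
            pump_present=p.get("pump_present", False),
            jitter=jitter,
        )
    return profiles


def profile_library() -> dict[str, SpeciesProfile]:
    """The ten studied species, with targets at the published statistics."""
    return load_profiles()
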