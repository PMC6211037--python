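# Methods

## The analysis chain

Duet recordings are conditioned exactly as the feature definitions require:
stereo WAV files are reduced to one channel (left by default; the analysis
uses a single channel and no convention for which one exists, so the choice
is configurable), downsampled to 44.1 kHz when recorded at 48 or 96 kHz,
high-pass filtered at 80 Hz (the titi fundamental lies above 100 Hz, so
this only strips wind and handling rumble), and peak-normalized to full
scale.  Filters are 4th-order Butterworth sections applied
forward–backward: the magnitude response is then 8th-order and the phase
exactly zero, so syllable onsets used by the temporal features are not
shifted.  Resampling is polyphase with a Kaiser(8) anti-aliasing window,
which preserves the 80–2000 Hz analysis band to well under 1%.

The power spectrum of a duet is the average of squared-magnitude spectra
over non-overlapping 2048-sample Hann windows (trailing partial window
discarded), max-normalized so the largest bin is 1.  At 44.1 kHz this gives
a 21.5 Hz bin.  Amplitude versus squared-amplitude is genuinely ambiguous
in "relative amplitude" conventions; squared magnitude (power) was chosen,
and every downstream quantity used comparatively (peak location, cumulative
ordering) is insensitive to that choice.

**Dominant frequency** is the largest of the five largest local maxima in
80–2000 Hz.  A local maximum requires strictly smaller neighbors; a plateau
is credited to its lowest-frequency bin; equal-power peaks tie toward the
lower frequency.  These tie rules are arbitrary but documented and tested.
The search band is deliberately the full 80–2000 Hz even though observed
peaks concentrate below 1500 Hz — the narrower range is an observation, not
a constraint.

**Cumulative spectra** are running sums of band power normalized to 1 at
the band top.  The *halfway frequency* (where the cumulative fraction
reaches 0.5) is computed by treating each bin's mass as spread uniformly
over the bin width, i.e. linear interpolation between bin upper edges with
an anchor at zero below the first bin.  This convention makes a
single-bin spectrum return exactly that bin's frequency and a flat spectrum
return the band midpoint, which the alternatives (interpolating between bin
centers, or a discrete quantile) do not both satisfy.

**Sequences** are delimited by the first onsets of male pant phrases; the
trailing unbounded interval is discarded, so k marker onsets yield k−1
sequences.  Phrase runs are recovered from the annotations by splitting
each voice's per-label event stream wherever consecutive onsets are more
than 1.2 s apart; within-phrase intervals never exceed ~0.8 s at the call
rates of these taxa, while the same phrase type recurs no sooner than
~1.6 s into the next sequence.  The two voices overlap in time, so
grouping must be per-voice: global adjacency would interleave concurrent
phrases.  Per-duet features are arithmetic means over that duet's
sequences and phrases (the duet, one per family group, is the sampling
unit; the aggregator is not fixed by the feature definitions and the mean
is the simplest unbiased choice).

## Statistics

Group summaries printed as mean ± SEM with n are converted to variances by
s² = n·SEM²; the ANOVA F and two-sample t computed from summaries equal the
raw-data statistics exactly (tested to 1e-10), so reconstructed values
carry only the rounding error of the printed inputs (≈1%).

The exact signed-rank null is built by convolving the rank indicator
polynomials — equivalent to enumerating all 2ⁿ sign assignments, feasible
to n = 25 — with midranks (doubled to keep an integer grid) when magnitudes
tie.  Two-sided p = min(1, 2·min(P(V ≤ v), P(V ≥ v))).  Beyond n = 25 a
normal approximation with continuity correction is used.  The rank-sum
statistic W is reported as the rank sum of the first sample minus its
minimum (Mann–Whitney U), so complete separation gives W = 0; its exact
null uses the subset-sum recursion over ranks when there are no ties.

The mixed model is the one Gaussian case the analysis needs: a random
intercept per duet with species as a fixed categorical factor.  The
variance ratio λ = σ²_b/σ²_e is profiled out of the REML criterion
(block-diagonal Woodbury identities keep each evaluation O(n)) and
optimized on log λ ∈ [−12, 12]; σ²_e and the GLS fixed effects follow in
closed form.  With one measurement per duet the criterion is flat in λ and
the intercept variance is unidentified; the boundary σ²_b = 0 is reported
and the fit reduces to OLS.  The analysis-of-deviance for the species
factor is a Wald χ² on the non-intercept coefficients (not a likelihood
ratio).  MANOVA statistics (Wilks Λ with Rao's F approximation, Pillai
trace) come from the eigenvalues of W⁻¹B; for two groups Pillai = 1 − Λ.

LDA standardizes features to z-scores before fitting (a transformation is
applied in the published workflow but not specified; z-scoring makes the
Fisher directions scale-invariant, which is tested).  Priors are class
proportions and the confusion matrix is resubstitution — no
cross-validation is attempted, matching the original analysis.  LD axes
are signed so the first class centroid projects positively on LD1.

## The synthetic duet generator

The generator exists because the original field recordings are not
deposited: it renders two-voice duets whose measurable statistics are
controlled, so feature extraction and the statistical battery can be tested
against known ground truth.  It emulates the hierarchical call structure —
syllables emitted in inhale/exhale pairs, phrases (runs of one syllable
type at a set rate), sequences (one pass through a per-species grammar,
delimited by the male pant phrase onset), and multi-sequence duets with
overlapping male and female voices.

Syllable acoustics are stylized: bellows are 5-harmonic stacks with a slow
±12 Hz vibrato; pants and terminal elements are band-limited noise bursts
12 dB below the loud syllables (matching the relative audibility of the
soft phrases); pumps are short high-rate bursts; arches and whinnies are
tonal FM sweeps; hoots are low narrowband tones.  The female voice's bellow
carrier sits 100 Hz above the male's (the published pair-level differences
span roughly 75–215 Hz), at 0.9× amplitude so the combined-signal peak
stays at the male carrier.  Species profiles (shipped as
`data/profiles.yaml`) set the grammar pattern and the targets — dominant
frequency, pant rate, sequence duration, pump/rhythmic rates, bellows per
sequence — to the published per-species statistics.  Timing jitter is
multiplicative Gaussian on onset intervals with CV 0.05 (truncated at 0.2
to keep onsets ordered); sequence periods jitter the same way.  Crescendo
and decrescendo bellow sub-phases are separate phrases with the published
rates (2.15 vs 2.53 calls/s), annotated `bellow-cre`/`bellow-dec`.

What the generator does **not** emulate: reverberation and habitat
filtering, amplitude modulation within syllables beyond a Tukey envelope,
formant structure or individual identity, imperfect voice coordination,
and overlapping background species (beyond an optional 6–7 kHz insect band
and broadband noise at a set SNR).  Passing round-trip tests therefore
show that the measurement chain is correct and unbiased at realistic
parameter values — not that it is robust to every field-recording
pathology.  Annotations are an input throughout, mirroring the manual
segmentation of the original workflow; no automatic syllable detection is
attempted.

One blank-versus-absent ambiguity in the published call inventory is
resolved conservatively: call types not reported for a species are simply
not synthesized, which is a modeling choice, not a claim about the
species' repertoire.

## Problem sizes and numerical choices

Tests synthesize at 22.05 kHz (all profile content tops out near 6.6 kHz)
with 2–4 sequences per duet and 10 seeds for round-trip properties; the
default pipeline renders 36 groups at 4 sequences each.  The
lineage-separation simulation draws 35 duets (donacophilus 9, moloch 20
with the reassigned taxon, torquatus 6) from the lineage-level summaries
with SD = SEM·√n and reports resubstitution accuracy over 100 seeded
repetitions; the simulated features are drawn independently within
lineage, which ignores the real positive correlation between dominant
frequency and pant rate and therefore makes the separation problem
slightly harder than the real data's.  Round-trip tolerances are one
spectral bin plus the sex offset for dominant frequency (the combined
spectrum's peak may land on either voice's bellow line), 5% for pant rate
and 10% for sequence duration (both dominated by the timing jitter).

## Known limitations

* The generator's spectra are line spectra plus noise bands; real duets
  have broadband energy whose dominant peak is less sharply defined.
* The mixed model covers only the single-random-intercept Gaussian case.
* Exact rank-sum p-values are computed only for untied samples up to a
  combined n of 25; ties always fall back to the corrected normal
  approximation.
* `wav` input mode expects Audacity label tracks with the
  `sex:phrase:syllable` convention; other annotation schemes must be
  converted first.
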