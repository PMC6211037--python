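# titiduet

Comparative acoustic analysis of titi monkey (Callicebinae) duets.

Titi monkeys are pair-bonded neotropical primates whose mated pairs produce
loud, coordinated vocal duets before dawn.  The three major *Plecturocebus* /
*Cheracebus* lineages — donacophilus, moloch, and torquatus — differ
systematically in three acoustic parameters of the combined (both-voice)
signal:

* **dominant frequency** — the frequency of the largest spectral peak of the
  whole duet within the 80–2000 Hz analysis band,
* **duet sequence duration** — the interval from the first male pant syllable
  of one sequence to the first male pant syllable of the next,
* **pant call rate** — within a pant phrase, (number of syllables − 1) /
  (span from first to last syllable onset).

`titiduet` implements the full analysis chain for these parameters, a
statistical battery (summary-reconstructed ANOVA and *t* tests, exact
Wilcoxon tests, Kruskal–Wallis, random-intercept mixed models, MANOVA,
Pearson correlation), and a Fisher linear discriminant analysis that
classifies duets into lineages.  Because field recordings of these duets are
not publicly deposited, the package includes a synthetic duet generator with
lineage-specific grammars whose acoustic and temporal targets are set to the
published per-species statistics; every downstream stage is tested against
that generator's ground truth.

## The core statistics

Fisher LDA seeks the direction *w* maximizing between-class relative to
within-class scatter; in the univariate two-class case this is the criterion

    J = (mu_1 - mu_2)^2 / (s_1^2 + s_2^2)

and in general the discriminant directions are the leading eigenvectors of
W⁻¹B (within- and between-class scatter matrices).  With three lineages and
three z-standardized predictors there are two discriminant axes (LD1, LD2);
classification uses the shared-covariance Gaussian rule with priors
proportional to class sizes, evaluated by resubstitution.

Several published group comparisons are reconstructed from printed
(mean ± SEM, *n*) summaries using s² = n·SEM²; the one-way ANOVA *F* and the
pooled/Welch *t* computed this way are algebraically identical to running
the tests on raw data with those moments.  Exact Wilcoxon signed-rank
p-values come from the full null distribution over all 2ⁿ sign assignments
(computed by convolution over the ranks).

## Worked example

Synthesize an annotated duet of a moloch-lineage species and extract its
features:

```sh
$ titiduet synth --species discolor --sequences 3 --seed 1 --out demo
wrote demo/discolor.wav (49.4 s, 165 syllables)

$ titiduet features demo/discolor.wav
{
  "dominant_frequency_hz": 990.53,
  "mean_sequence_duration_s": 15.415,
  "n_sequences": 3,
  "mean_pant_rate_cps": 3.359
}
```

The extracted values sit at the *P. discolor* profile targets (dominant
frequency 1004.0 Hz within one spectral-bin-plus-sex-offset tolerance —
the female voice's bellows are ~100 Hz above the male's and the combined
spectrum's peak can land on either — sequence duration 15.04 s and pant
rate 3.35 calls/s within the generator's 5% timing jitter).  The label
track (`demo/discolor.txt`) is an Audacity-compatible TSV with
`sex:phrase:syllable` labels, e.g. `f:bellow-cre:bellow` for a female
bellow in the crescendo sub-phase.

Run the full pipeline (36 synthetic family groups across ten species,
feature table, statistics report, two-stage LDA with biplots):

```sh
$ titiduet pipeline --seed 0 --out out
wrote out/report.json (36 duets analysed)
```

In `out/report.json` the first-stage LDA (all duets labeled with their
published lineage) misclassifies the moloch-patterned *P. urubambensis* out
of the donacophilus lineage, while the second stage (acoustic labels,
*P. oenanthe* excluded as a distinct vocal phenotype) classifies all 35
duets correctly.

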