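# Species profiles for the synthetic duet generator.
#
# Targets are the published per-species statistics: dominant frequency of the
# combined signal (group-level mean, Hz), pant call rate (group-level mean,
# calls/s), duet sequence duration (group-level mean where available,
# otherwise the species median, s), pump/rhythmic climax rates (calls/s) and
# male bellows per sequence.  `lineage` is the published (taxonomic) clade;
# `acoustic_lineage` is the clade whose duet pattern the species' loud call
# conforms to (they differ only for urubambensis, whose duet is moloch-like).
species:
  donacophilus:
    lineage: donacophilus
    pattern: donacophilus
    dominant_frequency_hz: 1202.8
    pant_rate_cps: 3.33
    sequence_duration_s: 4.83
    rhythmic_rate_cps: 4.1
  pallescens:
    lineage: donacophilus
    pattern: donacophilus
    dominant_frequency_hz: 1098.2
    pant_rate_cps: 3.52
    sequence_duration_s: 3.98
    rhythmic_rate_cps: 4.1
  olallae:
    lineage: donacophilus
    pattern: donacophilus
    dominant_frequency_hz: 1216.6
    pant_rate_cps: 3.53
    sequence_duration_s: 5.49
    rhythmic_rate_cps: 4.1
  modestus:
    lineage: donacophilus
    pattern: donacophilus
    dominant_frequency_hz: 947.5
    pant_rate_cps: 3.16
    sequence_duration_s: 6.34
    rhythmic_rate_cps: 4.1
  oenanthe:
    lineage: donacophilus
    acoustic_lineage: oenanthe
    pattern: oenanthe
    dominant_frequency_hz: 1464.2
    pant_rate_cps: 4.49
    sequence_duration_s: 20.82
  discolor:
    lineage: moloch
    pattern: moloch
    dominant_frequency_hz: 1003.99
    pant_rate_cps: 3.35
    sequence_duration_s: 15.04
    pump_rate_cps: 4.14
    bellow_rate_cre_cps: 2.15
    bellow_rate_dec_cps: 2.53
    bellows_range: [10, 12]
    pump_present: true
  toppini:
    lineage: moloch
    pattern: moloch
    dominant_frequency_hz: 978.22
    pant_rate_cps: 2.88
    sequence_duration_s: 13.61
    pump_rate_cps: 4.26
    bellow_rate_cre_cps: 2.15
    bellow_rate_dec_cps: 2.53
    bellows_range: [8, 10]
    pump_present: true
  aureipalatii:
    lineage: moloch
    pattern: moloch
    dominant_frequency_hz: 1012.1
    pant_rate_cps: 3.62
    sequence_duration_s: 11.16
    pump_rate_cps: 4.89
    bellow_rate_cre_cps: 2.15
    bellow_rate_dec_cps: 2.53
    bellows_range: [7, 9]
    pump_present: true
  urubambensis:
    lineage: donacophilus
    acoustic_lineage: moloch
    pattern: moloch
    dominant_frequency_hz: 839.8
    pant_rate_cps: 3.11
    sequence_duration_s: 13.89
    pump_rate_cps: 4.18
    bellow_rate_cre_cps: 2.15
    bellow_rate_dec_cps: 2.53
    bellows_range: [9, 11]
    pump_present: true
  lucifer:
    lineage: torquatus
    pattern: torquatus
    dominant_frequency_hz: 671.1
    pant_rate_cps: 2.05
    sequence_duration_s: 6.39
    phraseB_rate_cps: 1.39
    phraseC_rate_cps: 1.91
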