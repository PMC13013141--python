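# Total Improvement Score conversion table, transcribed from the 2016
# ACR/EULAR myositis response criteria for adult dermatomyositis/polymyositis.
#
# For each core-set measure the absolute percent improvement (change from
# baseline relative to the measure's total range, improvement positive) is
# binned at the listed thresholds; each bin awards the corresponding points.
# Improvements below the first threshold (including any worsening) score 0.
# Maximum total = 100.
measures:
  phga:      # physician global activity (TIS uses the 0-10 DM-specific scale)
    thresholds: [5, 15, 25, 40]
    points: [7.5, 15, 17.5, 20]
  ptga:      # patient global activity
    thresholds: [5, 15, 25, 40]
    points: [2.5, 5, 7.5, 10]
  mmt8:      # manual muscle testing
    thresholds: [2, 10, 20, 30]
    points: [10, 20, 27.5, 32.5]
  haq:       # health assessment questionnaire disability
    thresholds: [5, 15, 25, 40]
    points: [5, 7.5, 7.5, 10]
  enzyme:    # most abnormal muscle enzyme
    thresholds: [5, 15, 25, 40]
    points: [2.5, 5, 7.5, 7.5]
  exga:      # extramuscular global activity
    thresholds: [5, 15, 25, 40]
    points: [7.5, 12.5, 15, 20]

# Nested response categories on the total score.
categories:
  minimal: 20
  moderate: 40
  major: 60

# Span of the enzyme ULN-ratio scale used as its "total range" for percent
# improvement: the 90% natural-history range of the most abnormal enzyme,
# expressed in multiples of ULN.  Reference-derived default; configurable.
enzyme_range_span: 10.0
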