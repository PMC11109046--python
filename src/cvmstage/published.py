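"""Published performance figures of the original staging study.

The original development (n = 480, 120 per stage) and validation (n = 80,
20 per stage) cohorts are not deposited, but the printed per-stage
precision/recall pairs and cohort sizes are sufficient to reconstruct the
F1 scores and the overall accuracies arithmetically.  These constants feed
the cross-check suite and the reproduction script; they are inputs, not
outputs, of this package.

Known internal inconsistencies of the printed tables:

* modified model, validation cohort, iCS3: printed F1 0.9456 does not equal
  the harmonic mean of the printed precision/recall pair (0.9474, 0.9000),
  which is 0.9231; 0.9456 instead matches the text's overall validation F1.
  The printed pair is kept here; the printed F1 is stored separately as
  ``INCONSISTENT_F1`` and excluded from reconstruction checks.
* modified model, primary cohort, iCS3: the printed F1 0.9705 comes from
  unrounded counts (230/237); the harmonic mean of the rounded printed pair
  is 0.97044, which agrees to 1e-4.
"""

#: (precision, recall, printed F1) of the primary model, per stage.
PRIMARY_MODEL_PRIMARY_COHORT = {
    1: (0.9917, 1.0000, 0.9958),
    2: (0.9310, 0.9000, 0.9152),
    3: (0.8770, 0.8917, 0.8843),
    4: (0.9587, 0.9667, 0.9627),
}

PRIMARY_MODEL_VALIDATION_COHORT = {
    1: (1.0000, 1.0000, 1.0000),
    2: (0.9474, 0.9000, 0.9231),
    3: (0.8500, 0.8500, 0.8500),
    4: (0.9048, 0.9500, 0.9268),
}

#: The corrected (cascade) model is reported for the two confusable stages.
MODIFIED_MODEL_PRIMARY_COHORT = {
    3: (0.9829, 0.9583, 0.9705),
    4: (0.9594, 0.9833, 0.9712),
}

MODIFIED_MODEL_VALIDATION_COHORT = {
    3: (0.9474, 0.9000, None),  # printed F1 inconsistent, see module docstring
    4: (0.9048, 0.9500, 0.9268),
}

#: The internally inconsistent printed value, kept for documentation.
INCONSISTENT_F1 = 0.9456

N_PER_STAGE_PRIMARY = 120
N_PER_STAGE_VALIDATION = 20

#: Printed overall accuracies (percent).
ACCURACY_PRIMARY_PCT = 93.96
ACCURACY_VALIDATION_PCT = 92.50

#: Pooled means of the primary-model terms in the development cohort.
POOLED_FEATURE_MEANS = {"age": 11.50, "D3_AH3": 0.11, "ang4": 7.74,
                        "C3lp_C4up": 3.62}
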