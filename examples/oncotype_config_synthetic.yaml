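# SYNTHETIC example of a recurrence-score configuration.
# The published gene-group coefficients are not redistributed; this file
# only illustrates the schema the calculator consumes. Replace genes,
# weights and the affine calibration with the published values to reproduce
# the real score.
reference_genes: [REFA, REFB, REFC]
groups:
  stromal:
    genes: [STR1, STR2, STR3]
    weight: 5.0
  cell_cycle:
    genes: [CC1, CC2]
    weight: 8.0
  genomic_stability:
    genes: [GS1]
    weight: -4.0
intercept: 30.0
slope: 1.0
# risk categories applied to the resulting score:
#   rs < 30 -> low, 30 <= rs <= 40 -> intermediate, rs > 40 -> high
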