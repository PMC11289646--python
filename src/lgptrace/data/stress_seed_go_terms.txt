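# Seed GO terms for stress-relevant annotation (31 parent terms).
# Descendant closure over is_a (and optionally part_of) is taken before use.
GO:0001666
GO:0002931
GO:0003299
GO:0006952
GO:0006970
GO:0006979
GO:0006991
GO:0009271
GO:0009408
GO:0009409
GO:0009413
GO:0009414
GO:0009611
GO:0009635
GO:0033554
GO:0033555
GO:0034059
GO:0034405
GO:0035900
GO:0035902
GO:0035966
GO:0042594
GO:0051409
GO:0051599
GO:0055093
GO:0061771
GO:0080134
GO:0090664
GO:0097501
GO:0097532
GO:1990911
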