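# Term weights for the internal simplified ddG estimator (kcal/mol per unit term).
# These are interpretable heuristic weights for synthetic pipelines, not fitted
# to any experimental stability data.
term	weight
clash	0.05
hbond_loss	0.5
hydropathy	0.25
disulfide_loss	4.0
ca_loss	2.5
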