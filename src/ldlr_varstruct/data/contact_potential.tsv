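# Coarse residue-pair contact log-odds potential ("dope-like"), in arbitrary
# energy units. Classes: H = hydrophobic (AVILMFWC), P = polar (GSTYNQH),
# C = charged (DEKR). Bins are Cbeta-Cbeta distance ranges in Angstrom.
# Negative = favorable. Hand-designed so that tight hydrophobic packing is
# rewarded and buried like-charge contacts penalized; not derived from the PDB.
class_a	class_b	bin_lo	bin_hi	value
H	H	0	4	-1.0
H	H	4	6	-0.6
H	H	6	8	-0.2
H	H	8	10	0.0
H	P	0	4	0.2
H	P	4	6	0.0
H	P	6	8	0.0
H	P	8	10	0.0
H	C	0	4	0.6
H	C	4	6	0.3
H	C	6	8	0.0
H	C	8	10	0.0
P	P	0	4	0.0
P	P	4	6	0.0
P	P	6	8	0.0
P	P	8	10	0.0
P	C	0	4	0.0
P	C	4	6	0.0
P	C	6	8	0.0
P	C	8	10	0.0
C	C	0	4	0.8
C	C	4	6	0.4
C	C	6	8	0.1
C	C	8	10	0.0
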