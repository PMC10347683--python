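# Synthetic stand-in: a DS2-style molecular characterization of binge eating
# disorder built from the genes of the published reverted-protein table.
# Effector signs are not published for these genes and are imputed here
# (sign_imputed=true) as the direction opposite to the expected drug effect.
gene	sign	motive	sign_imputed
BDNF	-1	Neurotransmission alteration in impulse control circuitry	true
CRHR1	1	Deregulation of appetite mechanisms	true
NTRK2	-1	Neurotransmission alteration in impulse control circuitry	true
SLC18A2/VMAT2	1	Neurotransmission alteration in impulse control circuitry	true
SLC6A2/NET1	1	Neurotransmission alteration in impulse control circuitry	true
SLC6A3/DAT1	1	Neurotransmission alteration in impulse control circuitry	true
SLC6A4/SERT	1	Neurotransmission alteration in impulse control circuitry	true
TAAR1	-1	Neurotransmission alteration in impulse control circuitry	true
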