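gene	motives	adhd_effector
BDNF	Neurotransmission alteration in impulse control circuitry	Yes
CRHR1	Deregulation of appetite mechanisms	No
NTRK2	Neurotransmission alteration in impulse control circuitry	Yes
SLC18A2/VMAT2	Neurotransmission alteration in impulse control circuitry	No
SLC6A2/NET1	Neurotransmission alteration in impulse control circuitry	Yes
SLC6A3/DAT1	Neurotransmission alteration in impulse control circuitry	Yes
SLC6A4/SERT	Neurotransmission alteration in impulse control circuitry	No
TAAR1	Neurotransmission alteration in impulse control circuitry	No
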