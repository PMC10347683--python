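gene	motives	adhd_effector	population
BDNF	HPA axis hyperactivation/Loss of neural plasticity and Neurogenesis	Yes	Both
CCL2	Neuroinflammation	No	Both
CREB1	Loss of neural plasticity and neurogenesis	Yes	Both
CRH	HPA axis hyperactivation/Neuroinflammation	No	Both
CRHR1	HPA axis hyperactivation	No	Both
CRP	Neuroinflammation	Yes	Both
CXCL8	Neuroinflammation	No	Both
DRD2	Neurotransmission alteration	Yes	Both
EEF2K	Loss of neural plasticity and neurogenesis	No	Both
FGF1	Loss of neural plasticity and Neurogenesis/Neuroinflammation	No	Both
GSK3A	Loss of neural plasticity and neurogenesis	No	Both
GSK3B	Loss of neural plasticity and neurogenesis	No	Adult
HTR1A	Neurotransmission alteration	No	Both
IFNG	Neuroinflammation	Yes	Adult
IFNGR1	Neurotransmission alteration	No	Both
IFNGR2	Neurotransmission alteration	No	Both
IKBKB	Loss of neural plasticity and neurogenesis	No	Both
IL18	Neuroinflammation	No	Both
IL1A	Neuroinflammation	Yes	Both
IL1B	Neuroinflammation	Yes	Both
IL2	Neuroinflammation	Yes	Adult
IL6	Neuroinflammation	Yes	Both
MAO	Neurotransmission alteration	Yes	Both
MMP2	Neuroinflammation	No	Both
MTOR	Loss of neural plasticity and neurogenesis	Yes	Both
NFKB1	Loss of neural plasticity and Neurogenesis/Neuroinflammation	Yes	Both
NLRP3	Neuroinflammation	No	Both
NOS2	Neurotransmission alteration	No	Both
NR3C1	HPA axis hyperactivation	No	Both
NTRK2	HPA axis hyperactivation	Yes	Both
POMC	HPA axis hyperactivation	No	Both
PPARGC1A	Glutamatergic excitotoxicity/Neuroinflammation	No	Both
PRKACA	Loss of neural plasticity and neurogenesis	Yes	Both
PRKACB	Loss of neural plasticity and neurogenesis	Yes	Both
RAC1	Loss of neural plasticity and neurogenesis	No	Both
RPS6KB1	Loss of neural plasticity and neurogenesis	No	Both
RPS6KB2	Loss of neural plasticity and neurogenesis	No	Both
SERPINE1	Loss of neural plasticity and neurogenesis	No	Both
SLC6A2/NET1	Neurotransmission alteration	Yes	Both
SLC6A3/DAT1	Neurotransmission alteration	Yes	Both
SLC6A4/SERT	Neurotransmission alteration	No	Both
SMAD2	Neuroinflammation	No	Both
SMAD4	Neuroinflammation	No	Adult
SOD1	Oxidative stress	No	Adult
SOD2	Oxidative stress	No	Both
STAT1	Neuroinflammation	No	Both
TIMP2	Neuroinflammation	No	Both
TNF	HPA axis hyperactivation/Neuroinflammation	Yes	Both
VAMP2	Glutamatergic excitotoxicity	No	Both
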