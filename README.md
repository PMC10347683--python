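# comornet

Network-pharmacology modelling of whether a drug's protein targets can
revert the molecular state of a disease's comorbidities.

Psychiatric disorders such as ADHD rarely come alone: most patients carry
comorbidities (depression, anxiety, binge eating disorder, ...) whose
molecular descriptions overlap substantially with the primary disorder. A
natural question is whether a drug designed against the primary disorder
also counteracts, at the protein level, the signatures of the
comorbidities. `comornet` implements an in-silico pipeline to study exactly
that, for researchers in systems pharmacology and computational psychiatry:

1. **Characterization.** Each disease is a set of *protein effectors* —
   gene symbols with the activation direction $s_g \in \{-1, +1\}$ that
   induces the disease — grouped into pathophysiological *motives*. A drug
   is a signed target set (effect $+1$ activation, $-1$ inhibition).
2. **Interactome.** Edge lists from heterogeneous sources (SIF or TSV) are
   merged into a deduplicated protein-protein interaction network with
   optional per-edge sign/direction; overlap statistics report which
   fraction of a base disease's effectors is shared with, or directly
   connected to, each comorbidity's.
3. **Relationship scoring.** Closest-distance network proximity
   $d(T, E) = \frac{1}{|T|}\sum_{t \in T} \min_{e \in E}\,\mathrm{dist}(t, e)$
   of the target set $T$ to an effector set $E$, calibrated against a
   degree-matched permutation null. The empirical p-value maps onto a
   0–100 score through fixed anchors so that bands correspond to p-value
   thresholds (score $\geq 92 \leftrightarrow p<0.01$;
   $77$–$92 \leftrightarrow p<0.05$; $37$–$77 \leftrightarrow p<0.25$;
   $<37 \leftrightarrow p \geq 0.25$).
4. **Virtual patients.** Truncated-normal cohorts (default 100 patients per
   age category; floor 71) and a linear 14-compartment, flow-limited PBPK
   model with first-order oral absorption and renal clearance, scaled
   allometrically per patient; the shipped default parameter set for the
   LDX active metabolite is calibrated to an oral bioavailability of 96.4%.
5. **Network models.** Sampled signed-propagation models over the
   interactome: activities follow
   $a(t{+}1) = \tanh\!\big(s + W^\top a(t)\big)$ with stimulus nodes
   clamped, so $a \in [-1,1]^n$. Solutions (edge-weight vectors) are
   accepted only if they reproduce at least 85% of the training
   stimulus/response restrictions. Drug exposure enters as an Emax stimulus
   $\mathrm{effect}_g \cdot C/(C + EC_{50})$ from each patient's brain
   concentration curve.
6. **Mechanism-of-action outcomes.** An effector is *reverted* when its
   predicted activity opposes its disease sign with $|a| > 0.5$; the
   tSignal is the signed mean $\frac{1}{|E|}\sum_g a_g s_g$ (negative = net
   reversion); mechanism paths are $\leq 3$-edge interactome paths from a
   drug target to a strongly reverted effector ($|a| > 0.8$), kept only at
   100% population frequency with sign-consistent weights.

The proximity score and the propagation model are declared, reproducible
surrogates for proprietary components of the methodology they emulate (a
trained relationship-scoring network and the sampling machinery behind it);
they preserve the published interfaces — score bands, bounded activities,
the accuracy floor — without claiming to reproduce unpublished internals.

## Worked example

The numbered drivers under `analysis/` run the whole study on a synthetic
universe (no downloads needed):

```bash
python analysis/01_characterize_overlap.py
python analysis/02_score_relationships.py
python analysis/03_virtual_population.py
python analysis/04_network_models.py
python analysis/05_mechanisms.py
```

Stage 1 prints, for the packaged 7-target drug table and a 6-disease
synthetic universe generated at a realistic sharing regime:

```
drug vLDX: 7 targets (1 activated, 6 inhibited)
base disease shares 53.3% of its effectors with >=1 comorbidity
per-comorbidity sharing: disease_1=33.3%, disease_2=20.0%, disease_3=15.0%, disease_4=11.7%, disease_5=8.3%
shared or directly connected: 95.0%
```

i.e. half the base disorder's effectors appear in at least one comorbidity,
and almost all are at most one interaction away from one. Stage 3 prints

```
oral bioavailability of the default parameter set: 96.4%
adult: n=100, brain Cmax 1.80 +/- 0.26 mg/L at t=1.7 h
pediatric: n=100, brain Cmax 3.20 +/- 0.93 mg/L at t=1.7 h
```

— the AUC-ratio bioavailability of the shipped parameter set, and the
per-cohort brain exposure after a 70 mg oral dose (higher in children
because clearance scales with weight^0.75). Stage 4 prints

```
accepted 10 solutions on 1000 nodes / 2991 edges
training accuracy: min 0.850, mean 0.851, max 0.860 (floor 0.85)
```

— every sampled network model meets the 85% training-compliance floor.
Stage 5 runs the per-patient chain and tallies reverted effectors, the
tSignal and the filtered mechanism paths, and pushes the packaged
published-style reverted-protein tables through the same population
bookkeeping (8 reverted effectors for the eating-disorder table, 4 of them
flagged as base-disorder effectors; 49 adult / 44 pediatric for the
depression table).

A YAML-driven end-to-end run is also available:

```bash
comornet run-all --config src/comornet/data/toy_config.yaml --outdir /tmp/toy
```

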