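# J/K-like synthetic scenario on the 14-bin ~10-Myr scheme (J1..K8).
# Shapes: a richness ramp through the Jurassic bins, one high-extinction
# bin at the end-Jurassic (J6), suppressed origination through the three
# following bins, and a five-fold sampling crash in the two bins directly
# after the event (K1, K2).
name: jk_like
n0: 40
bins: tenmyr
# per-bin origination rate (per taxon per bin):   J1...J6, K1...K8
lambda: [0.35, 0.35, 0.35, 0.35, 0.35, 0.30, 0.08, 0.08, 0.08, 0.25, 0.25, 0.25, 0.25, 0.25]
# per-bin extinction rate; the J6 spike is the boundary event
mu:     [0.15, 0.15, 0.15, 0.15, 0.15, 0.90, 0.20, 0.15, 0.15, 0.15, 0.15, 0.15, 0.15, 0.15]
# per-bin sampling intensity (expected occurrences per living taxon);
# K1 and K2 are the post-event sampling crash (5x drop)
sampling: [2.5, 2.5, 2.5, 2.5, 2.5, 2.5, 0.5, 0.5, 2.5, 2.5, 2.5, 2.5, 2.5, 2.5]
collections_per_bin: 25
pubs_per_bin: 8
age_smear: 0.0
polytomy_fraction: 0.3
driver:
  name: sea_level
  beta: 0.8
  phi: 0.3
  sigma: 0.3
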