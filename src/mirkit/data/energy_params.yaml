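# Simplified nearest-neighbor folding parameters (kcal/mol at 37C).
# Stacks are indexed outer-pair -> inner-pair, where the outer pair (X, Y)
# closes positions (i, j) and the inner pair closes (i+1, j-1).
# Loop penalties are by total unpaired length; lengths beyond the tables are
# extrapolated as E(Lmax) + coef * ln(L / Lmax).
stack:
  AU: {AU: -0.9, CG: -2.2, GC: -2.1, UA: -1.1, GU: -0.6, UG: -1.4}
  CG: {AU: -2.1, CG: -3.3, GC: -2.4, UA: -2.1, GU: -1.4, UG: -2.1}
  GC: {AU: -2.4, CG: -3.4, GC: -3.3, UA: -2.2, GU: -1.5, UG: -2.5}
  UA: {AU: -1.3, CG: -2.4, GC: -2.1, UA: -0.9, GU: -1.0, UG: -1.3}
  GU: {AU: -1.3, CG: -2.5, GC: -2.1, UA: -1.4, GU: -0.5, UG: -0.4}
  UG: {AU: -1.0, CG: -1.5, GC: -1.4, UA: -0.6, GU: -0.2, UG: -0.5}
hairpin: {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.4}
bulge: {1: 3.8, 2: 2.8, 3: 3.2, 4: 3.6, 5: 4.0, 6: 4.4}
internal: {2: 1.7, 3: 1.8, 4: 2.0, 5: 2.2, 6: 2.5}
extrapolation_coef: 1.078
multiloop:
  closing: 3.4
  branch: 0.4
  unpaired: 0.1
min_hairpin: 3
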