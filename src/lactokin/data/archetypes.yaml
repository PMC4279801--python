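# Nine kinetic archetype profiles (log2 ratio vs. time 0) used by the
# synthetic generator. Hand-written step/ramp shapes qualitatively matching
# the nine observed cluster behaviours: up-regulated clusters 1, 5, 7-9 and
# down-regulated clusters 2, 3, 4, 6. Condition order within each strain is
# 1 h, 3 h, 6 h, 24 h after the start of lactose feeding.
#
# Magnitudes avoid the +-1 selection boundary so that the generator's
# regulated/unregulated ground truth is unambiguous, and same-direction
# profiles are kept near-equidistant (pairwise Euclidean distance ~4-6)
# so the archetypes are separable at the default noise level of 0.3 log2
# units.
1:
  description: early up-regulation (1 h) in NG 14 only
  NG14: [2.5, 3.0, 2.5, 2.0]
  RUTC30: [0.0, 0.0, 0.0, 0.0]
2:
  description: down from 3 h in NG 14, weaker and retarded repression in RUT C30
  NG14: [0.0, -2.0, -2.0, -2.5]
  RUTC30: [0.0, -0.5, -2.0, -3.0]
3:
  description: early down-regulation (1 h) in NG 14 only
  NG14: [-3.0, -2.5, -2.0, -1.5]
  RUTC30: [0.0, 0.0, 0.0, 0.0]
4:
  description: down from 3 h in NG 14 only, deeper repression
  NG14: [0.0, -3.0, -3.5, -3.5]
  RUTC30: [0.0, 0.0, 0.0, 0.0]
5:
  description: late up-regulation at 24 h in RUT C30 only
  NG14: [0.0, 0.0, 0.0, 0.0]
  RUTC30: [0.0, 0.0, 0.5, 4.0]
6:
  description: down-regulation in RUT C30 only
  NG14: [0.0, 0.0, 0.0, 0.0]
  RUTC30: [0.0, -0.5, -3.0, -4.0]
7:
  description: up-regulation at 6 h in NG 14 only
  NG14: [0.0, 0.0, 3.0, 3.0]
  RUTC30: [0.0, 0.0, 0.0, 0.0]
8:
  description: early up-regulation in both strains, shared amplitude
  NG14: [2.0, 2.5, 2.5, 3.0]
  RUTC30: [2.0, 2.5, 2.5, 3.0]
9:
  description: early strong up-regulation in both strains, higher in NG 14
  NG14: [4.0, 4.5, 4.5, 5.0]
  RUTC30: [1.5, 2.0, 2.0, 2.5]
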