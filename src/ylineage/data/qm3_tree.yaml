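# Packaged Q-M3 subtree of the Y-chromosome haplogroup Q hierarchy.
#
# Provenance notes (this file is data, not code — amend freely):
# - Trunk order Q-M242 > L56 > M346 > L54 > {M3, Z780, CTS11780} > M848
#   follows the consortium hierarchy for the autochthonous American Q clades.
# - The CO15..CO27 sublineages descend from the CO24/CO27 clade under M848.
#   Their branch order is reconstructed from the relative coalescence ages
#   of the sublineages and from the two clusters the correspondence analysis
#   of the defining SNPs separates; it is a reading of a published figure,
#   not of machine-readable data, so treat the CO branch order as amendable.
# - CO24/CO27 and CO16/CO25 are phyloequivalent marker pairs (one clade each).
# - Literature markers CTS11357, SA05 (with Z19319 below it), Z5915 and
#   Z19483 are placed as additional branches under Q-M848.
root: Q-M242
nodes:
  - {name: Q-M242, markers: [M242], parent: null}
  - {name: Q-L56, markers: [L56], parent: Q-M242}
  - {name: Q-M346, markers: [M346], parent: Q-L56}
  - {name: Q-L54, markers: [L54], parent: Q-M346}
  - {name: Q-M3, markers: [M3], parent: Q-L54}
  - {name: Q-Z780, markers: [Z780], parent: Q-L54}
  - {name: Q-CTS11780, markers: [CTS11780], parent: Q-L54}
  - {name: Q-M848, markers: [M848], parent: Q-M3}
  # literature sublineages under M848
  - {name: Q-CTS11357, markers: [CTS11357], parent: Q-M848}
  - {name: Q-SA05, markers: [SA05], parent: Q-M848}
  - {name: Q-Z19319, markers: [Z19319], parent: Q-SA05}
  - {name: Q-Z5915, markers: [Z5915], parent: Q-M848}
  - {name: Q-Z19483, markers: [Z19483], parent: Q-M848}
  # new CO sublineages
  - {name: Q-CO24/CO27, markers: [CO24, CO27], parent: Q-M848}
  # clade A (deep to shallow)
  - {name: Q-CO15, markers: [CO15], parent: Q-CO24/CO27}
  - {name: Q-CO16/CO25, markers: [CO16, CO25], parent: Q-CO15}
  - {name: Q-CO19, markers: [CO19], parent: Q-CO16/CO25}
  - {name: Q-CO21, markers: [CO21], parent: Q-CO19}
  - {name: Q-CO18, markers: [CO18], parent: Q-CO21}
  - {name: Q-CO20, markers: [CO20], parent: Q-CO18}
  # clade B (deep to shallow)
  - {name: Q-CO22, markers: [CO22], parent: Q-CO24/CO27}
  - {name: Q-CO26, markers: [CO26], parent: Q-CO22}
  - {name: Q-CO17, markers: [CO17], parent: Q-CO26}
  - {name: Q-CO23, markers: [CO23], parent: Q-CO17}
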