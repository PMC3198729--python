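# Ordinal disruption scores for guide:target base alignments, written
# target_base:guide_base. 0 = canonical Watson-Crick pairing; larger values
# indicate alignments expected to disrupt the guide/target A-form helix more.
#
# Provenance: editorial ordering chosen for this toolkit, consistent with the
# mismatch-strength literature on allele-specific silencing: G:U wobble is
# near-canonical (weakest discriminating alignment), purine:purine alignments
# are the most disruptive (two double-ring bases between the backbones), and
# C:C is more disruptive than A:C or U:C. The exact integer values are a
# documented choice, not a measured quantity; supply your own table to
# override.
provenance: >-
  sirnawalk default ordinal table: WC=0 < wobble=1 < A:C/U:C=2 < U:U=3 <
  C:C/purine:purine=4-5. Editorial; see docs/methods.md.
scores:
  "A:U": 0
  "U:A": 0
  "G:C": 0
  "C:G": 0
  "G:U": 1
  "U:G": 1
  "A:C": 2
  "C:A": 2
  "U:C": 2
  "C:U": 2
  "U:U": 3
  "C:C": 4
  "A:G": 4
  "G:A": 4
  "A:A": 4
  "G:G": 5
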