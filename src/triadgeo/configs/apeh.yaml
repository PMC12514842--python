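# Porcine acylpeptide hydrolase (pAPEH), author numbering of the ligand-free
# deposition 7PX8 and the complexes 9GNE / 9GOU / 9HXQ.
#
# Provenance notes
# ----------------
# - Triad, oxyanion donors and the oxyanion-loop range (508-511) are taken
#   from the published description of the active site.
# - The core segments are meant to be the backbone of the eight beta-strands
#   of the central sheet of the hydrolase domain plus the helix immediately
#   following the catalytic Ser.  Exact strand boundaries are not published;
#   the ranges below are curated estimates pending verification against the
#   secondary-structure annotation of the local copy of 7PX8 (verified: false).
#   Override this file once the deposition is available locally.
# - The ligand block must name the deposited ligand residue and its key atoms
#   (tetrahedral/phosphoryl oxygen, amide nitrogen); these are read from the
#   deposition and are not published in the text, so it ships empty here.
name: pAPEH
accessions: [7PX8, 9GNE, 9GOU, 9HXQ]
verified_core: false

triad:
  ser: {res_name: SER, seq: 587}
  his: {res_name: HIS, seq: 707}
  asp: {res_name: ASP, seq: 675}
ser_og: OG

oxyanion_donors:
  - {res_name: GLY, seq: 509, atom: N}   # distal donor; d2/d3 heteroatom
  - {res_name: HIS, seq: 588, atom: N}
distal_donor_index: 0

oxyanion_loop: {start: 508, end: 511}
his_loop: {start: 703, end: 710}

# Eight central beta-strands (estimates; see provenance notes) + post-Ser helix.
core:
  - {start: 503, end: 507}
  - {start: 520, end: 525}
  - {start: 545, end: 550}
  - {start: 563, end: 568}
  - {start: 580, end: 585}
  - {start: 650, end: 655}
  - {start: 670, end: 674}
  - {start: 697, end: 702}
  - {start: 588, end: 600}   # helix following the catalytic Ser

# ligand: {res_name: ???, atoms: [O1, N1]}   # fill in from the deposition
ligand: null

measure_atoms:
  - {res_name: GLY, seq: 509, atom: N}
  - {res_name: GLY, seq: 509, atom: CA}
  - {res_name: HIS, seq: 707, atom: CA}

contacts:
  - label: Arg677NE-Asp624OD1
    a: {res_name: ARG, seq: 677, atom: NE}
    b: {res_name: ASP, seq: 624, atom: OD1}
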