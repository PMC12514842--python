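# Human dipeptidyl peptidase 4 (DPP-IV).  Special case: the canonical
# oxyanion-loop amide is replaced by the hydroxyl of Tyr547, so the distal
# donor heteroatom for d2/d3 is that sidechain oxygen.  (Published tables
# write "TyrOG1" for this atom; standard Tyr nomenclature has no OG1 - the
# hydroxyl oxygen is "OH", which is what this config uses.)
# Core segment ranges are curated estimates (verified: false).
name: DPP4
accessions: []
verified_core: false

triad:
  ser: {res_name: SER, seq: 630}
  his: {res_name: HIS, seq: 740}
  asp: {res_name: ASP, seq: 708}
ser_og: OG

oxyanion_donors:
  - {res_name: TYR, seq: 547, atom: OH}  # distal donor: sidechain hydroxyl O
  - {res_name: TYR, seq: 631, atom: N}
distal_donor_index: 0

oxyanion_loop: {start: 545, end: 549}
his_loop: {start: 736, end: 742}

core:
  - {start: 600, end: 605}
  - {start: 620, end: 625}
  - {start: 650, end: 655}
  - {start: 700, end: 705}
  - {start: 726, end: 731}
  - {start: 660, end: 665}
  - {start: 685, end: 690}
  - {start: 708, end: 713}
  - {start: 631, end: 642}   # helix following the catalytic Ser

ligand: null
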