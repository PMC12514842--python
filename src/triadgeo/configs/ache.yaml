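# Human acetylcholinesterase, author numbering of the recombinant human
# enzyme depositions.  The acidic member of the triad is a glutamate; the
# "asp" slot of the site definition holds whichever acidic residue the
# enzyme uses.  Core segment ranges are curated estimates (verified: false).
name: AChE
accessions: [1j06, 2y2v, 2jgm, 2jgk]
verified_core: false

triad:
  ser: {res_name: SER, seq: 203}
  his: {res_name: HIS, seq: 447}
  asp: {res_name: GLU, seq: 334}
ser_og: OG

oxyanion_donors:
  - {res_name: GLY, seq: 121, atom: N}   # distal donor
  - {res_name: GLY, seq: 122, atom: N}
  - {res_name: ALA, seq: 204, atom: N}
distal_donor_index: 0

oxyanion_loop: {start: 118, end: 124}
his_loop: {start: 443, end: 450}

core:
  - {start: 100, end: 105}
  - {start: 140, end: 145}
  - {start: 170, end: 175}
  - {start: 196, end: 201}
  - {start: 222, end: 227}
  - {start: 320, end: 325}
  - {start: 400, end: 405}
  - {start: 440, end: 442}
  - {start: 204, end: 215}   # helix following the catalytic Ser

ligand: null

measure_atoms:
  - {res_name: GLY, seq: 121, atom: N}
  - {res_name: HIS, seq: 447, atom: CA}
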