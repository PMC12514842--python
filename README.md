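# triadgeo

Active-site geometry and plasticity analysis for serine hydrolases:

- **structure I/O** — PDB / mmCIF parsing (Bio.PDB backed) into an explicit
  chain → residue → atom model with a deterministic altloc policy (highest
  occupancy, ties to the smallest altloc id) and author residue numbering;
- **superposition** — Kabsch least-squares rigid fitting (reflections
  excluded) and per-chain *core superposition* on configured backbone
  segments, the frame in which all loop shifts are measured;
- **site metrics** — the d1/d2/d3 active-site "spaciousness" triangle
  (Cα(Ser)–Cα(His), Cα(Ser)–distal oxyanion donor heteroatom,
  donor–Cα(His)), apo→holo loop shifts with toward/away classification
  against the ligand centroid (or Ser Oγ fallback), pairwise contacts,
  inclusive 3.5 Å H-bond classification, and apo/holo delta tables;
- **SASA** — a deterministic Shrake–Rupley implementation (golden-spiral
  lattice, covariant per-atom orientation giving exact rigid-motion
  invariance, grid neighbor search identical to all-pairs) specialized to
  the catalytic-Ser sidechain accessibility;
- **ensemble analysis** — pairwise RMSD over main-chain + Cβ atoms,
  GROMOS-style neighbor-counting clustering at a 1 Å cutoff, per-frame Ser
  SASA series, and a deterministic two-component Gaussian-mixture EM fit;
- **synthetic fixtures** — generators for toy hydrolases, apo/holo pairs
  with planted transforms and loop shifts, sphere systems with analytic
  SASA, and two-state ensembles with recorded ground truth.

## CLI

```sh
triadgeo compare apo.pdb holo.pdb --site apeh --out out/   # shifts, triangles, contacts
triadgeo panel manifest.yaml --out out/                    # cross-enzyme delta table
triadgeo ensemble frames.pdb --site toy.yaml --out out/    # clustering + SASA mixture fit
triadgeo sasa model.pdb --site apeh --out out/             # per-atom SASA report
triadgeo fixtures --seed 1 --out fx/                       # synthetic fixture files
triadgeo fetch 7PX8 --out data/structures                  # explicit network access
```

`--site` takes a YAML path or the name of a curated config shipped in
`src/triadgeo/configs/` (`apeh`, `ache`, `dpp4`). Site configs declare the
catalytic triad, oxyanion donors (with the distal-donor choice that defines
d2/d3, including the DPP4-style sidechain-oxygen special case), loop
segments, the core segments used for superposition, and optional ligand key
atoms. JSON outputs embed provenance (tool version, config hash, input
checksums).

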