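# Deposited structure drop-in directory

Place local copies of the deposited coordinate files here (lowercase stem,
`.cif`, `.pdb` or `.ent`), e.g. `7px8.cif`, `9gne.cif`, `9gou.cif`,
`9hxq.cif`. The paper-value acceptance tests and `scripts/acceptance.py`
look for them at this path.

On a networked machine:

```sh
triadgeo fetch 7PX8 9GNE 9GOU 9HXQ --out data/structures
```

This sandbox has no route to any PDB mirror, so the directory ships empty.
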