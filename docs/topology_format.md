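# The JSON topology dialect

The canonical fixture/interchange format (`"format":
"qmmmkit-topology-1"`) carries everything the toolkit needs in one
file: structure, connectivity, charges, residue partition and
(optionally) the MM term table.  Units are Å, e and kJ/mol.

```json
{
 "format": "qmmmkit-topology-1",
 "atoms": [
  {"name": "CA", "element": "C", "residue_id": 0,
   "residue_name": "ALA", "position": [1.45, 0.35, 0.15],
   "charge": -0.032, "serial": null}
 ],
 "bonds": [[0, 1]],
 "residues": [
  {"id": 0, "name": "ALA", "atoms": [0, 1], "formal_charge": 0}
 ],
 "terms": {
  "bonds":    [[[0, 1], [1000.0, 1.48]]],
  "angles":   [[[0, 1, 2], [300.0, 1.91]]],
  "torsions": [[[0, 1, 2, 3], [[4.0, 2.0, 3.14159]]]],
  "lj":       [[0, [0.3598, 3.4]]],
  "hl_lj":    [0.0657, 2.471],
  "scale_elec_14": 0.8333333333333334,
  "scale_lj_14": 0.5
 },
 "provenance": {"tool": "qmmmkit", "version": "0.1.0", "parameters": {}}
}
```

Field notes:

* `atoms` are implicitly indexed 0..n−1 in order; `serial` preserves a
  1-based PDB serial when the system came from a PDB file.
* `residues[*].atoms` must partition the atom indices exactly;
  `formal_charge` is an integer in e.
* `terms.bonds` maps an atom pair to `(k, r0)` for `k (r − r0)^2`;
  `terms.angles` to `(k, θ0)` in rad for `k (θ − θ0)^2`;
  `terms.torsions` to a series of `(V, n, γ)` for `V (1 + cos(nφ − γ))`;
  `terms.lj` to per-atom `(ε, σ)` combined by Lorentz–Berthelot.
  `hl_lj` is the `(ε, σ)` pair used when a junction M1 atom is
  substituted by a hydrogen link atom.
* Round-tripping through `write_json_topology` / `read_json_topology`
  preserves charges to better than 1e-10 e and bond sets exactly.

The `fixtures` CLI subcommand writes this format alongside a PDB;
the `junctions`, `charges`, `assemble` and `bigqm` subcommands read
it.
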