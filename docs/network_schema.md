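# Network file schema

`osteosim` exchanges signaling topologies as plain JSON so variants can be
tested without code changes (`osteosim.network.save_network` /
`load_network`, CLI stage `osteosim network`).

```json
{
 "species":  {"<name>": "dynamic" | "algebraic" | "input", ...},
 "edges":    [{"source": "...", "target": "...",
               "sign": "activate" | "inhibit",
               "weight": 1.0,
               "source_form": "phospho" | "unphospho"}, ...],
 "pairs":    [["<phospho>", "<base>", "<total_id>"], ...],
 "ligand_bindings": [["<ligand>", "<free receptor>", "<complex>"], ...],
 "totals":   {"<total_id>": 1.0, ...}
}
```

* `dynamic` species carry an ODE; `algebraic` species are computed from a
  conservation pair (`base = total − phospho`); `input` species are
  externally prescribed (the ligands BMP2 and IGF1).
* Every algebraic species appears in exactly one pair; every dynamic
  species has a positive total `C_<name>` in `totals`.
* `weight` is a fixed structural multiplier (default 1.0); `source_form`
  selects whether the phosphorylated or the unphosphorylated pool of the
  source acts (the GSK3β → β-catenin edge uses `"unphospho"`).
* Parameter ids are derived from the structure
  (`osteosim.network.kinetic_parameter_ids`): `a_<s>`/`d_<s>` for each
  conservation-paired dynamic species, `a_<s>` for each unpaired (TF)
  species, plus the shared `d_TF`.  The canonical network yields exactly
  37.

The canonical topology padding (which proteins are tracked as paired
dynamic species, which as TF sinks) is recorded in the serialized file
itself and discussed in `docs/methods.md`.
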