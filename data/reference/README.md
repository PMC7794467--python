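# Reference structures (user-supplied)

The crystal-structure and deposited-model checks in `tests/test_acceptance.py`
compute geometric descriptors from published structures that are **not
redistributed** with this package.  To run those checks, download the files
below into this directory (plain PDB format, original author numbering):

| file              | source                                                |
|-------------------|-------------------------------------------------------|
| `1bvy.pdb`        | RCSB PDB entry 1BVY (P450 BM3 heme + FMN domains)     |
| `3qe2.pdb`        | RCSB PDB entry 3QE2 (closed-form CPR)                 |
| `3es9.pdb`        | RCSB PDB entry 3ES9 (open/semi-open CPR)              |
| `ma-7au7g.pdb`    | ModelArchive ma-7au7g (D2′ membrane-complex final frame) |

`reference_config.yaml` must define the helix selections that have no
canonical numeric range (they are never inferred silently):

```yaml
onebvy:
  heme_chain: A        # heme-domain chain paired with the FMN domain
  fmn_chain: B
  c_helix: [[A, 121, 138]]   # C-helix Cα range of the heme domain (user-assigned)
ma7au7g:
  cyp_globular: [[51, 513]]
  fmn_domain: [[66, 230]]
```

Without these files the corresponding acceptance tests fail with an
explanatory message; every other test is self-contained.
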