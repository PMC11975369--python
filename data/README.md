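# data/

Optional reference inputs (not distributed with the package).

- `1bd2.pdb` — place a copy of PDB entry 1BD2 (B7 TCR–Tax/HLA-A2
  crystal structure, https://www.rcsb.org/structure/1BD2) here to
  enable the crystal-structure CDR3-distance check in
  `tests/test_acceptance.py` and the corresponding entry in
  `scripts/acceptance.py`.  Without it that single test fails with an
  explanatory message; everything else is self-contained.
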