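# Default electron-donating-group registry.
#
# ids 1-3 are authoritative (named in the source screening campaign);
# ids 4-9 are clearly-flagged placeholder EDGs chosen only so the class
# partition (3 weak + 2 moderate + 4 strong) holds.  Enumeration and
# counting logic never depends on fragment identity.
#
# `fragment` is a SMILES fragment graftable inside a branch; ring-closure
# digits >= 2 to avoid clashing with the scaffold ring.
substituents:
  - id: 1
    label: methyl
    strength: weak
    fragment: "C"
    authoritative: true
  - id: 2
    label: 2-methyl-2-butene
    strength: weak
    fragment: "CC(C)=CC"
    authoritative: true
  - id: 3
    label: phenyl
    strength: weak
    fragment: "c2ccccc2"
    authoritative: true
  - id: 4
    label: methoxy (placeholder)
    strength: moderate
    fragment: "OC"
    authoritative: false
  - id: 5
    label: acetamido (placeholder)
    strength: moderate
    fragment: "NC(C)=O"
    authoritative: false
  - id: 6
    label: hydroxy (placeholder)
    strength: strong
    fragment: "O"
    authoritative: false
  - id: 7
    label: amino (placeholder)
    strength: strong
    fragment: "N"
    authoritative: false
  - id: 8
    label: methylamino (placeholder)
    strength: strong
    fragment: "NC"
    authoritative: false
  - id: 9
    label: dimethylamino (placeholder)
    strength: strong
    fragment: "N(C)C"
    authoritative: false
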