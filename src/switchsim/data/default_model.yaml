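# Default segment-granularity folding model (ligand present, pausing at PS1).
# One state per (length class, conformation, ligand status); block synthesis
# steps carry rates matching the mean per-nucleotide transit times, including
# the 70-fold slowdown across U107-U112.  Regenerate with
#   build_default_model(SimulationConfig(ligand_present=True, granularity="segment")).to_yaml(...)
states:
- id: P@75
  position: 75
  helices: []
  ligand_bound: false
  role: elongating
- id: PA@89
  position: 89
  helices:
  - PA
  ligand_bound: false
  role: elongating
- id: '[PA]T@134'
  position: 134
  helices:
  - PA
  ligand_bound: false
  role: elongating
- id: P[AT]@134
  position: 134
  helices:
  - AT
  ligand_bound: false
  role: elongating
- id: P[AT]@164
  position: 164
  helices:
  - AT
  ligand_bound: false
  role: elongating
- id: '[PA][TH]@164'
  position: 164
  helices:
  - PA
  - TH
  ligand_bound: false
  role: elongating
- id: readthrough
  position: 165
  helices: []
  ligand_bound: false
  role: readthrough
- id: terminated
  position: 164
  helices:
  - PA
  - TH
  ligand_bound: false
  role: terminated
- id: ligPA@89
  position: 89
  helices:
  - PA
  ligand_bound: true
  role: elongating
- id: ligPA*@89
  position: 89
  helices:
  - PA
  ligand_bound: true
  role: elongating
- id: lig[PA]T@134
  position: 134
  helices:
  - PA
  ligand_bound: true
  role: elongating
- id: lig[PA]T@164
  position: 164
  helices:
  - PA
  ligand_bound: true
  role: elongating
- id: lig[PA][TH]@164
  position: 164
  helices:
  - PA
  - TH
  ligand_bound: true
  role: elongating
- id: ligP[AT]@164
  position: 164
  helices:
  - AT
  ligand_bound: true
  role: elongating
transitions:
- source: P@75
  target: PA@89
  rate: 1.4285714285714284
  kind: synthesis
- source: PA@89
  target: '[PA]T@134'
  rate: 0.04357298474945531
  kind: synthesis
- source: '[PA]T@134'
  target: P[AT]@134
  rate: 0.009
  kind: folding
- source: P[AT]@134
  target: P[AT]@164
  rate: 0.6666666666666664
  kind: synthesis
- source: P[AT]@164
  target: '[PA][TH]@164'
  rate: 0.0005
  kind: folding
- source: P[AT]@164
  target: readthrough
  rate: 20.0
  kind: synthesis
- source: '[PA][TH]@164'
  target: terminated
  rate: 20.0
  kind: termination_commit
- source: PA@89
  target: ligPA@89
  rate: 0.24
  kind: ligand_binding
- source: ligPA@89
  target: ligPA*@89
  rate: 0.018
  kind: folding
- source: ligPA@89
  target: lig[PA]T@134
  rate: 0.04357298474945531
  kind: synthesis
- source: ligPA*@89
  target: lig[PA]T@134
  rate: 0.04357298474945531
  kind: synthesis
- source: lig[PA]T@134
  target: lig[PA]T@164
  rate: 0.6666666666666664
  kind: synthesis
- source: P[AT]@134
  target: lig[PA]T@134
  rate: 0.00089
  kind: ligand_binding
- source: P[AT]@164
  target: lig[PA]T@164
  rate: 0.00089
  kind: ligand_binding
- source: lig[PA]T@164
  target: lig[PA][TH]@164
  rate: 0.14
  kind: folding
- source: lig[PA][TH]@164
  target: terminated
  rate: 20.0
  kind: termination_commit
- source: P[AT]@164
  target: ligP[AT]@164
  rate: 0.02
  kind: ligand_binding
- source: ligP[AT]@164
  target: lig[PA][TH]@164
  rate: 0.0012
  kind: folding
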