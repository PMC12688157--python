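# Declarative version of the two-state selective binder design.
# Run with:  foldscape run examples/selective_binder.yaml --out scratch/binder_run
chains:
  - id: binder
    sequence: ARNDAGKE
    mutable: true
  - id: target
    sequence: KLMNPQW
    mutable: false
  - id: off_target
    sequence: QRSTVDE
    mutable: false

states:
  - name: bind
    chains: [binder, target]
    terms:
      - term: PAEEnergy
        weight: 1.0
        oracle: fold
        groups:
          - {chain: binder, residues: all}
          - {chain: target, residues: all}
  - name: avoid
    chains: [binder, off_target]
    terms:
      - term: PAEEnergy
        weight: -1.0
        oracle: fold
        groups:
          - {chain: binder, residues: all}
          - {chain: off_target, residues: all}

oracles:
  fold:
    type: ToyFoldOracle
    position_skip: 512

protocol:
  type: Canonical
  n_mut: 1

minimizer:
  type: SimulatedTempering
  t_low: 0.02
  t_high: 0.5
  n_low: 40
  n_high: 10
  n_cycles: 10
  seed: 7
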