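layers:
- name: Input
  size: 27
  k_active: 5
  gain: 80.0
  inhib_floor: 0.02
  rel_floor: 0.25
  dt: 0.4
- name: EC_in
  size: 27
  k_active: 5
  gain: 80.0
  inhib_floor: 0.02
  rel_floor: 0.25
  dt: 0.4
- name: EC_out
  size: 27
  k_active: 5
  gain: 80.0
  inhib_floor: 0.02
  rel_floor: 0.25
  dt: 0.4
- name: DG
  size: 400
  k_active: 8
  gain: 80.0
  inhib_floor: 0.02
  rel_floor: 0.25
  dt: 0.4
- name: CA3
  size: 80
  k_active: 16
  gain: 80.0
  inhib_floor: 0.02
  rel_floor: 0.25
  dt: 0.4
- name: CA1
  size: 100
  k_active: 20
  gain: 80.0
  inhib_floor: 0.02
  rel_floor: 0.25
  dt: 0.4
projections:
- src: Input
  dst: EC_in
  connectivity_fraction: 1.0
  learnable: false
  learning_rate: 0.0
  pathway: fixed
  phase_gates: {}
  weight_init:
  - 0.25
  - 0.75
  identity: true
  exclude_self: false
  strength: 1.0
  hebbian: 0.0
  hebbian_rate: null
  columnar: false
  exclude_own_column: false
  decay: 0.0
- src: EC_out
  dst: EC_in
  connectivity_fraction: 1.0
  learnable: false
  learning_rate: 0.0
  pathway: fixed
  phase_gates:
    test_initial: 0.0
  weight_init:
  - 0.25
  - 0.75
  identity: true
  exclude_self: false
  strength: 0.5
  hebbian: 0.0
  hebbian_rate: null
  columnar: false
  exclude_own_column: false
  decay: 0.0
- src: EC_in
  dst: DG
  connectivity_fraction: 0.25
  learnable: false
  learning_rate: 0.0
  pathway: TSP
  phase_gates: {}
  weight_init:
  - 0.0
  - 0.2
  identity: false
  exclude_self: false
  strength: 1.0
  hebbian: 0.0
  hebbian_rate: null
  columnar: false
  exclude_own_column: false
  decay: 0.0
- src: EC_in
  dst: CA3
  connectivity_fraction: 0.25
  learnable: true
  learning_rate: 0.1
  pathway: TSP
  phase_gates: {}
  weight_init:
  - 0.0
  - 0.2
  identity: false
  exclude_self: false
  strength: 1.0
  hebbian: 1.0
  hebbian_rate: 0.4
  columnar: false
  exclude_own_column: false
  decay: 0.0
- src: DG
  dst: CA3
  connectivity_fraction: 0.05
  learnable: false
  learning_rate: 0.0
  pathway: TSP
  phase_gates:
    test: 0.0
    test_initial: 0.0
  weight_init:
  - 0.0
  - 0.2
  identity: false
  exclude_self: false
  strength: 32.0
  hebbian: 0.0
  hebbian_rate: null
  columnar: false
  exclude_own_column: false
  decay: 0.0
- src: CA3
  dst: CA3
  connectivity_fraction: 1.0
  learnable: true
  learning_rate: 0.1
  pathway: TSP
  phase_gates: {}
  weight_init:
  - 0.0
  - 0.2
  identity: false
  exclude_self: true
  strength: 1.0
  hebbian: 1.0
  hebbian_rate: 0.4
  columnar: false
  exclude_own_column: false
  decay: 0.0
- src: CA3
  dst: CA1
  connectivity_fraction: 1.0
  learnable: true
  learning_rate: 0.1
  pathway: TSP
  phase_gates:
    trough: 0.0
  weight_init:
  - 0.0
  - 0.2
  identity: false
  exclude_self: false
  strength: 2.0
  hebbian: 0.0
  hebbian_rate: null
  columnar: false
  exclude_own_column: false
  decay: 0.0
- src: EC_in
  dst: CA1
  connectivity_fraction: 1.0
  learnable: true
  learning_rate: 0.01
  pathway: MSP
  phase_gates:
    peak: 0.0
    plus: 0.0
  weight_init:
  - 0.0
  - 0.2
  identity: false
  exclude_self: false
  strength: 1.0
  hebbian: 0.0
  hebbian_rate: null
  columnar: false
  exclude_own_column: true
  decay: 0.0
- src: CA1
  dst: EC_out
  connectivity_fraction: 1.0
  learnable: true
  learning_rate: 0.1
  pathway: MSP
  phase_gates: {}
  weight_init:
  - 0.3
  - 0.7
  identity: false
  exclude_self: false
  strength: 1.0
  hebbian: 0.0
  hebbian_rate: null
  columnar: true
  exclude_own_column: false
  decay: 0.0
- src: EC_out
  dst: CA1
  connectivity_fraction: 1.0
  learnable: true
  learning_rate: 0.1
  pathway: MSP
  phase_gates: {}
  weight_init:
  - 0.3
  - 0.7
  identity: false
  exclude_self: false
  strength: 1.0
  hebbian: 0.0
  hebbian_rate: null
  columnar: true
  exclude_own_column: false
  decay: 0.0
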