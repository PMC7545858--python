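# Built-in scenario-variation parameter sets of the HEMS cost study.
#
# Scenarios 1/2/3 differ by daily operating hours (12 h / 16 h / 24 h), which
# drives personnel cost, night-vision equipment and the night-mission counts.
# Variations I-V per scenario: I initial assumptions, II high cost
# assumptions, III dual-use service (more secondary transfers), IV static
# rope, V rescue winch.
#
# Monetary values in euro, durations in minutes, areas in km^2.  Maintenance
# intervals are [threshold, price] pairs; flight-time thresholds are engine
# MINUTES.  q may be a fraction string such as "4/7".

shared:
  i: 120.0        # medical material per primary mission
  j: 170.0        # medical material per secondary mission
  l: 5.83         # fuel per engine minute
  t: 2            # starts per mission
  beta: 11550.0   # primary operating area
  gamma: 23000.0  # secondary operating area
  b_x: 20.0
  b_y: 20.0
  b_z: 45.0
  b_w: 45.0
  price_per_minute: 70.0

defaults:
  start_intervals: &starts_standard
    - [200, 4200.0]
    - [400, 8000.0]
    - [1200, 50000.0]
    - [2400, 100000.0]
  start_intervals_high: &starts_high
    - [200, 4200.0]
    - [400, 9000.0]
    - [1200, 55000.0]
    - [2400, 110000.0]
  flighttime_intervals: &flighttime_standard
    - [3000, 1000.0]
    - [6000, 3000.0]
    - [18000, 14000.0]
    - [36000, 40000.0]
  flighttime_intervals_high: &flighttime_high
    - [3000, 1000.0]
    - [6000, 3000.0]
    - [18000, 15000.0]
    - [36000, 45000.0]
  winch_intervals: &winch
    - [1, 100.0]
    - [20, 3000.0]
  special_static_rope: &static_rope
    alpha: 0.05
    m: 1.5
    n: 2.0
    r: 300
    s: 20.0
    o: 10000.0
    v: 39980.0
  special_winch: &winch_equipment
    alpha: 0.1
    m: 0.5
    n: 2.0
    r: 100
    s: 60.0
    o: 45000.0
    v: 94980.0

scenarios:
  "1.I":
    description: "12 h operations, initial cost assumptions"
    a: 316450.0
    p: 724000.0
    q: 1
    profile: {y: 0, z: 92, w: 0}
    start_intervals: *starts_standard
    flighttime_intervals: *flighttime_standard
  "1.II":
    description: "12 h operations, high cost assumptions"
    a: 657000.0
    p: 842000.0
    q: 1
    profile: {y: 0, z: 92, w: 0}
    start_intervals: *starts_high
    flighttime_intervals: *flighttime_high
  "1.III":
    description: "12 h operations, dual-use service"
    a: 316450.0
    p: 724000.0
    q: 1
    profile: {y: 0, z: 400, w: 0}
    start_intervals: *starts_standard
    flighttime_intervals: *flighttime_standard
  "1.IV":
    description: "12 h operations, static rope"
    a: 316450.0
    p: 734000.0
    q: 1
    profile: {y: 0, z: 92, w: 0}
    start_intervals: *starts_standard
    flighttime_intervals: *flighttime_standard
    special: *static_rope
  "1.V":
    description: "12 h operations, rescue winch"
    a: 316450.0
    p: 769000.0
    q: 1
    profile: {y: 0, z: 92, w: 0}
    start_intervals: *starts_standard
    flighttime_intervals: *flighttime_standard
    winch_intervals: *winch
    special: *winch_equipment
  "2.I":
    description: "16 h operations, initial cost assumptions"
    a: 338450.0
    p: 869000.0
    q: 1
    profile: {y: 0, z: 92, w: 0}
    start_intervals: *starts_standard
    flighttime_intervals: *flighttime_standard
  "2.II":
    description: "16 h operations, high cost assumptions"
    a: 648200.0
    p: 1004000.0
    q: 1
    profile: {y: 0, z: 92, w: 0}
    start_intervals: *starts_high
    flighttime_intervals: *flighttime_high
  "2.III":
    description: "16 h operations, dual-use service"
    a: 338450.0
    p: 869000.0
    q: 1
    profile: {y: 0, z: 400, w: 0}
    start_intervals: *starts_standard
    flighttime_intervals: *flighttime_standard
  "2.IV":
    description: "16 h operations, static rope"
    a: 338450.0
    p: 879000.0
    q: 1
    profile: {y: 0, z: 92, w: 0}
    start_intervals: *starts_standard
    flighttime_intervals: *flighttime_standard
    special: *static_rope
  "2.V":
    description: "16 h operations, rescue winch"
    a: 338450.0
    p: 914000.0
    q: 1
    profile: {y: 0, z: 92, w: 0}
    start_intervals: *starts_standard
    flighttime_intervals: *flighttime_standard
    winch_intervals: *winch
    special: *winch_equipment
  "3.I":
    description: "24 h operations, initial cost assumptions"
    a: 338450.0
    p: 1286000.0
    q: "4/7"
    profile: {y: 120, z: 92, w: 140}
    start_intervals: *starts_standard
    flighttime_intervals: *flighttime_standard
  "3.II":
    description: "24 h operations, high cost assumptions"
    a: 679000.0
    p: 1490000.0
    q: "4/7"
    profile: {y: 120, z: 92, w: 140}
    start_intervals: *starts_high
    flighttime_intervals: *flighttime_high
  "3.III":
    description: "24 h operations, dual-use service"
    a: 338450.0
    p: 1286000.0
    q: "4/7"
    profile: {y: 120, z: 400, w: 140}
    start_intervals: *starts_standard
    flighttime_intervals: *flighttime_standard
  "3.IV":
    description: "24 h operations, static rope"
    a: 338450.0
    p: 1306000.0
    q: "5/9"
    profile: {y: 120, z: 92, w: 140}
    start_intervals: *starts_standard
    flighttime_intervals: *flighttime_standard
    special: *static_rope
  "3.V":
    description: "24 h operations, rescue winch"
    a: 338450.0
    p: 1331000.0
    q: "4/7"
    profile: {y: 120, z: 92, w: 140}
    start_intervals: *starts_standard
    flighttime_intervals: *flighttime_standard
    winch_intervals: *winch
    special: *winch_equipment
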