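{
  "version": 1,
  "description": "Declarative dead-end inhibition rule table for two-substrate kinetic mechanism calls, following Cleland-style pattern logic. Cells: analog_a_vs_a / analog_a_vs_b (dead-end analog of substrate A varied against A / B) and analog_b_vs_a / analog_b_vs_b. Labels: C competitive, MT mixed, NC noncompetitive (mixed with alpha = 1), UC uncompetitive. Rules are evaluated in order; the first match wins.",
  "geometries": ["intersecting_on_1s_axis", "intersecting_left", "parallel"],
  "labels": ["C", "MT", "NC", "UC"],
  "rules": [
    {
      "name": "parallel_initial_velocity",
      "when": {"geometry": ["parallel"]},
      "call": "ambiguous",
      "annotation": "parallel initial-velocity lines suggest a ping-pong or highly ordered pattern outside the sequential rule table"
    },
    {
      "name": "analog_of_A_uncompetitive_vs_B",
      "when": {"analog_a_vs_b": ["UC"]},
      "call": "ordered_A_first",
      "annotation": "uncompetitive pattern of the A-analog against B places A upstream of B"
    },
    {
      "name": "analog_of_B_uncompetitive_vs_A",
      "when": {"analog_b_vs_a": ["UC"]},
      "call": "ordered_B_first",
      "annotation": "uncompetitive pattern of the B-analog against A places B upstream of A"
    },
    {
      "name": "random_sequential",
      "when": {
        "geometry": ["intersecting_on_1s_axis", "intersecting_left"],
        "analog_a_vs_a": ["C"],
        "analog_b_vs_b": ["C"],
        "analog_a_vs_b": ["C", "MT", "NC"],
        "analog_b_vs_a": ["C", "MT", "NC"]
      },
      "call": "rapid_equilibrium_random",
      "annotation": "each analog competitive versus its own substrate, neither uncompetitive versus the co-substrate"
    }
  ],
  "default_call": "ambiguous",
  "extra_annotations": [
    {
      "when": {"analog_b_vs_a": ["C"]},
      "annotation": "B-analog competitive versus A: the analog and A may occupy the same site"
    },
    {
      "when": {"analog_a_vs_b": ["C"]},
      "annotation": "A-analog competitive versus B: the analog and B may occupy the same site"
    }
  ],
  "standing_annotation": "dead-end patterns alone cannot distinguish rapid-equilibrium from steady-state random binding"
}
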