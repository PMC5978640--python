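{
 "al_square": {
  "center": [
   0.0,
   30.0,
   21.0
  ],
  "contrast": 0.2,
  "size": [
   10.0,
   10.0,
   2.0
  ]
 },
 "alignment_markers": [
  {
   "center": [
    -29.0,
    8.0,
    18.0
   ],
   "contrast": 1.0,
   "diameter": 3.0
  },
  {
   "center": [
    29.0,
    8.0,
    24.0
   ],
   "contrast": 1.0,
   "diameter": 3.0
  },
  {
   "center": [
    -29.0,
    91.0,
    24.0
   ],
   "contrast": 1.0,
   "diameter": 3.0
  },
  {
   "center": [
    29.0,
    91.0,
    18.0
   ],
   "contrast": 1.0,
   "diameter": 3.0
  }
 ],
 "background_attenuation": 1.0,
 "gauges": [
  {
   "contrast": 0.6,
   "gauge_id": "gauge_0",
   "lateral_position": -24.0,
   "n_steps": 12,
   "step_increment": 0.5,
   "thickness": 2.0,
   "width": 2.0,
   "z_center": 21.0
  },
  {
   "contrast": 0.6,
   "gauge_id": "gauge_1",
   "lateral_position": -8.0,
   "n_steps": 12,
   "step_increment": 0.5,
   "thickness": 2.0,
   "width": 2.0,
   "z_center": 21.0
  },
  {
   "contrast": 0.6,
   "gauge_id": "gauge_2",
   "lateral_position": 8.0,
   "n_steps": 12,
   "step_increment": 0.5,
   "thickness": 2.0,
   "width": 2.0,
   "z_center": 21.0
  },
  {
   "contrast": 0.6,
   "gauge_id": "gauge_3",
   "lateral_position": 24.0,
   "n_steps": 12,
   "step_increment": 0.5,
   "thickness": 2.0,
   "width": 2.0,
   "z_center": 21.0
  }
 ],
 "low_contrast_spheres": [
  {
   "center": [
    8.572527594031472e-16,
    44.0,
    21.0
   ],
   "contrast": 0.02,
   "diameter": 1.0
  },
  {
   "center": [
    -8.99902653561155,
    40.72462220366569,
    21.0
   ],
   "contrast": 0.02,
   "diameter": 1.5
  },
  {
   "center": [
    -13.787308542170912,
    32.43107448733702,
    21.0
   ],
   "contrast": 0.02,
   "diameter": 0.8
  },
  {
   "center": [
    -12.12435565298214,
    23.0,
    21.0
   ],
   "contrast": 0.02,
   "diameter": 10.0
  },
  {
   "center": [
    -4.78828200655936,
    16.844303308997283,
    21.0
   ],
   "contrast": 0.02,
   "diameter": 2.0
  },
  {
   "center": [
    4.788282006559366,
    16.844303308997283,
    21.0
   ],
   "contrast": 0.02,
   "diameter": 8.0
  },
  {
   "center": [
    12.124355652982137,
    22.999999999999993,
    21.0
   ],
   "contrast": 0.02,
   "diameter": 3.0
  },
  {
   "center": [
    13.787308542170914,
    32.43107448733702,
    21.0
   ],
   "contrast": 0.02,
   "diameter": 6.0
  },
  {
   "center": [
    8.999026535611554,
    40.72462220366569,
    21.0
   ],
   "contrast": 0.02,
   "diameter": 4.0
  }
 ],
 "overall_thickness": 42.0,
 "ramps": [
  {
   "bead_diameter": 0.18,
   "bead_pitch": 2.0,
   "contrast": 25.0,
   "lateral_position": -24.0,
   "limb_offset": 1.0,
   "ramp_id": "ramp_left",
   "side": "left",
   "total_rise": 10.0,
   "vertical_spacing": 0.25,
   "y_start": 10.0,
   "z_center": 21.0
  },
  {
   "bead_diameter": 0.18,
   "bead_pitch": 2.0,
   "contrast": 25.0,
   "lateral_position": 24.0,
   "limb_offset": 1.0,
   "ramp_id": "ramp_right",
   "side": "right",
   "total_rise": 10.0,
   "vertical_spacing": 0.25,
   "y_start": 50.0,
   "z_center": 21.0
  }
 ],
 "schema_version": 1,
 "x_range": [
  -32.0,
  32.0
 ],
 "y_range": [
  0.0,
  96.0
 ],
 "z_beads": [
  {
   "center": [
    20.0,
    64.0,
    11.0
   ],
   "contrast": 3.0,
   "diameter": 5.0
  },
  {
   "center": [
    20.0,
    64.0,
    21.0
   ],
   "contrast": 3.0,
   "diameter": 5.0
  },
  {
   "center": [
    20.0,
    64.0,
    31.0
   ],
   "contrast": 3.0,
   "diameter": 5.0
  }
 ]
}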