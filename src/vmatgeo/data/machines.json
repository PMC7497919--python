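{
 "schema_version": 1,
 "description": "MLC machine models: ordered leaf-pair Y-plane boundaries (mm at isocenter), jaw caps, field limits and default BEV distance criteria.",
 "machines": [
  {
   "name": "HD120",
   "mlc_type": "HD120",
   "leaf_pair_edges_mm": [
    -110.0,
    -105.0,
    -100.0,
    -95.0,
    -90.0,
    -85.0,
    -80.0,
    -75.0,
    -70.0,
    -65.0,
    -60.0,
    -55.0,
    -50.0,
    -45.0,
    -40.0,
    -37.5,
    -35.0,
    -32.5,
    -30.0,
    -27.5,
    -25.0,
    -22.5,
    -20.0,
    -17.5,
    -15.0,
    -12.5,
    -10.0,
    -7.5,
    -5.0,
    -2.5,
    0.0,
    2.5,
    5.0,
    7.5,
    10.0,
    12.5,
    15.0,
    17.5,
    20.0,
    22.5,
    25.0,
    27.5,
    30.0,
    32.5,
    35.0,
    37.5,
    40.0,
    45.0,
    50.0,
    55.0,
    60.0,
    65.0,
    70.0,
    75.0,
    80.0,
    85.0,
    90.0,
    95.0,
    100.0,
    105.0,
    110.0
   ],
   "max_field_x_mm": 400.0,
   "max_field_y_mm": 220.0,
   "sad_mm": 1000.0,
   "y_jaw_cap_mm": 40.0,
   "default_criteria": {
    "x_max_mm": 50.0,
    "y_max_mm": 40.0
   }
  },
  {
   "name": "M120",
   "mlc_type": "M120",
   "leaf_pair_edges_mm": [
    -200.0,
    -190.0,
    -180.0,
    -170.0,
    -160.0,
    -150.0,
    -140.0,
    -130.0,
    -120.0,
    -110.0,
    -100.0,
    -95.0,
    -90.0,
    -85.0,
    -80.0,
    -75.0,
    -70.0,
    -65.0,
    -60.0,
    -55.0,
    -50.0,
    -45.0,
    -40.0,
    -35.0,
    -30.0,
    -25.0,
    -20.0,
    -15.0,
    -10.0,
    -5.0,
    0.0,
    5.0,
    10.0,
    15.0,
    20.0,
    25.0,
    30.0,
    35.0,
    40.0,
    45.0,
    50.0,
    55.0,
    60.0,
    65.0,
    70.0,
    75.0,
    80.0,
    85.0,
    90.0,
    95.0,
    100.0,
    110.0,
    120.0,
    130.0,
    140.0,
    150.0,
    160.0,
    170.0,
    180.0,
    190.0,
    200.0
   ],
   "max_field_x_mm": 400.0,
   "max_field_y_mm": 400.0,
   "sad_mm": 1000.0,
   "y_jaw_cap_mm": null,
   "default_criteria": {
    "x_max_mm": 50.0,
    "y_max_mm": 50.0
   }
  }
 ]
}
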