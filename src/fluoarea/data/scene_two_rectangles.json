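{
  "distance_cm": 50.0,
  "scale_model": "pinhole_inverse_square",
  "focal_constant": 100.0,
  "width_px": 256,
  "height_px": 256,
  "wall_color": [50, 50, 50],
  "cast": [1.0, 1.0, 1.0],
  "gradient_amplitude": 0.0,
  "noise_sigma": 0.0,
  "seed": 0,
  "shapes": [
    {"kind": "rectangle", "x_mm": -15.0, "y_mm": 0.0, "width_mm": 40.0, "height_mm": 20.0, "color": [235, 80, 80]},
    {"kind": "rectangle", "x_mm": 25.0, "y_mm": 0.0, "width_mm": 20.0, "height_mm": 10.0, "color": [235, 80, 80]}
  ]
}
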