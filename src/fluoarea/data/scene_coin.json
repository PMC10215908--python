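{
  "distance_cm": 33.4,
  "scale_model": "pinhole_inverse_square",
  "focal_constant": 100.0,
  "width_px": 256,
  "height_px": 256,
  "wall_color": [96, 96, 96],
  "cast": [1.0, 1.0, 1.0],
  "gradient_amplitude": 0.0,
  "noise_sigma": 0.0,
  "seed": 0,
  "shapes": [
    {"kind": "disk", "x_mm": 0.0, "y_mm": 0.0, "radius_mm": 11.0, "color": [210, 210, 190]}
  ]
}
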