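{
  "description": "Summary of the 4,980-case single-centre primary TKA registry cohort (PFC Sigma system) that the default synthetic generator emulates.",
  "n_total": 4980,
  "counts": {
    "sex": {"male": 1826, "female": 3154},
    "side": {"left": 2366, "right": 2614},
    "femur_type": {"CR": 1569, "PS": 3411},
    "femur_size": {"1.5": 2, "2": 188, "2.5": 749, "3": 1616, "4N": 346, "4": 1130, "5": 866, "6": 83},
    "tibia_size": {"1.5": 2, "2": 312, "2.5": 1186, "3": 1648, "4": 1325, "5": 495, "6": 12},
    "insert_thickness_mm": {"8": 2413, "10": 1995, "12.5": 479, "15": 87, "17.5": 4, "20": 1, "22.5": 1},
    "patellar_resurfacing": {"true": 3902, "false": 1078}
  },
  "continuous": {
    "height_cm": {"mean": 168.6, "sd": 9.7},
    "weight_kg": {"mean": 85.3, "sd": 15.6},
    "bmi": {"mean": 30.1, "sd": 5.0}
  }
}
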