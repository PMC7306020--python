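{
  "_comment": [
    "Default fetal-head descent trajectories, piecewise-linear in station.",
    "Coordinate convention: anterior = +x (mm), caudal = +z (mm); station in",
    "cm on the obstetric scale relative to the ischial-spine plane (negative",
    "above).  Numeric anchors: occiput-posterior (OP) head enters at 45 deg",
    "internal rotation which completes at station +3; 20 deg flexion is",
    "reached in the midpelvis (station 0) and increases past the spine;",
    "total anterior displacement over the descent is 100.0 mm.  The",
    "anterior/caudal magnitudes at intermediate stations and the OA flexion",
    "profile are neutral placeholders, not measured values."
  ],
  "OP": {
    "presentation": "OP",
    "rotation_complete_station": 3.0,
    "waypoints": [
      {"station": -3.0, "anterior_mm": 0.0, "caudal_mm": 0.0, "internal_rotation_deg": 45.0, "flexion_deg": 0.0},
      {"station": 0.0, "anterior_mm": 45.0, "caudal_mm": 40.0, "internal_rotation_deg": 22.5, "flexion_deg": 20.0},
      {"station": 3.0, "anterior_mm": 75.0, "caudal_mm": 75.0, "internal_rotation_deg": 0.0, "flexion_deg": 26.0},
      {"station": 8.0, "anterior_mm": 100.0, "caudal_mm": 110.0, "internal_rotation_deg": 0.0, "flexion_deg": 45.0}
    ]
  },
  "OA": {
    "presentation": "OA",
    "rotation_complete_station": 0.0,
    "waypoints": [
      {"station": -3.0, "anterior_mm": 0.0, "caudal_mm": 0.0, "internal_rotation_deg": 45.0, "flexion_deg": 10.0},
      {"station": 0.0, "anterior_mm": 50.0, "caudal_mm": 45.0, "internal_rotation_deg": 0.0, "flexion_deg": 25.0},
      {"station": 3.0, "anterior_mm": 80.0, "caudal_mm": 80.0, "internal_rotation_deg": 0.0, "flexion_deg": 32.0},
      {"station": 8.0, "anterior_mm": 100.0, "caudal_mm": 105.0, "internal_rotation_deg": 0.0, "flexion_deg": 45.0}
    ]
  }
}
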