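{
  "comment": "Coarse Ramachandran region boxes in degrees, [phi_lo, phi_hi, psi_lo, psi_hi]. Core boxes cover the canonical alpha and beta basins; allowed boxes are generous supersets plus the left-handed alpha basin. These are this package's own simplified region definitions, not a published density grid.",
  "general": {
    "core": [[-115, -40, -70, -5], [-170, -45, 90, 180], [-170, -45, -180, -160]],
    "allowed": [[-180, -30, -120, 60], [-180, -30, 60, 180], [-180, -30, -180, -150], [30, 90, -20, 80]]
  },
  "gly": {
    "core": [[-115, -40, -70, -5], [-170, -45, 90, 180], [40, 115, 5, 70], [45, 170, -180, -90]],
    "allowed": [[-180, 0, -180, 180], [0, 180, -180, 180]]
  },
  "pro": {
    "core": [[-110, -40, -70, -5], [-110, -40, 110, 180]],
    "allowed": [[-180, -30, -120, 180], [-180, -30, -180, -150]]
  },
  "prepro": {
    "core": [[-115, -40, -70, -5], [-170, -45, 90, 180]],
    "allowed": [[-180, -30, -120, 60], [-180, -30, 60, 180], [-180, -30, -180, -150], [30, 90, -20, 80]]
  }
}
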