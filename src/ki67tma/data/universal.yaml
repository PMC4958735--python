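# Universal nucleus-classifier configuration.
#
# Calibrated once against the reference Ruifrok-Johnston H-E-DAB stain
# rendering used by the synthetic core generator.  HSI convention: hue in
# degrees [0, 360) (positive/DAB hue range wraps through 0), saturation and
# intensity on 0-255.  Sizes in micrometres; width/compactness/roundness/
# axis-ratio are object acceptance ranges, spot_width the nucleus-splitting
# scale.  Instrument-tuned parameter sets can be dropped in as alternate
# files with the same schema.
version: universal-1
classes:
  positive:
    hue: [330, 75]
    saturation: [35, 255]
    intensity: [25, 225]
    spot_width: 8.0
    width: [5.0, 16.0]
    compactness: [1.0, 2.5]
    roundness: [0.35, 1.0]
    axis_ratio: [1.0, 2.6]
  negative:
    hue: [195, 292]
    saturation: [22, 255]
    intensity: [25, 230]
    spot_width: 8.0
    width: [5.0, 16.0]
    compactness: [1.0, 2.5]
    roundness: [0.35, 1.0]
    axis_ratio: [1.0, 2.6]
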