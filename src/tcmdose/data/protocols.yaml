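# Chest protocol constants per scanner and tube voltage.
# ctdi_per_mas is the measured 32-cm dose-index output per effective mAs.
force_120:
  scanner: Force
  kvp: 120
  qrm: 140
  rotation_time_s: 0.5
  pitch: 0.6
  collimation_cm: 5.76
  bowtie: body
  hvl_mm_al: 8.0
  ctdi_per_mas: 0.115
flash_120:
  scanner: Flash
  kvp: 120
  qrm: 140
  rotation_time_s: 0.5
  pitch: 0.6
  collimation_cm: 3.84
  bowtie: body
  hvl_mm_al: 7.9
  ctdi_per_mas: 0.140
flash_100:
  scanner: Flash
  kvp: 100
  qrm: 269
  rotation_time_s: 0.5
  pitch: 0.6
  collimation_cm: 3.84
  bowtie: body
  hvl_mm_al: 6.8
  ctdi_per_mas: 0.087
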