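{
 "protocols": [
  {
   "protocol_id": "shimadzu_radiography",
   "device": "Shimadzu FH-21 HR",
   "modality": "radiography",
   "kVp": 59,
   "mAs": 12.6,
   "fov": "13x16 cm (AP+LAT)",
   "extra": {
    "filtration_mm_al": 1.5,
    "scan_height_mm": 130
   }
  },
  {
   "protocol_id": "siemens_msct",
   "device": "Siemens Sensation Open",
   "modality": "MSCT",
   "kVp": 120,
   "mAs": 115,
   "fov": "13x16 cm",
   "extra": {
    "CTDIvol_mGy": 11.0,
    "DLP_mGy_cm": 179,
    "filtration_mm_al": 6.8,
    "scan_angle_deg": 360,
    "slice_thickness_mm": 2,
    "pitch_mm": 0.5
   }
  },
  {
   "protocol_id": "newtom_hires_12x8",
   "device": "NewTom 5G",
   "modality": "CBCT",
   "kVp": 110,
   "mAs": 27.7,
   "fov": "12x8 cm HiRes",
   "extra": {
    "CTDIvol_mGy": 4.4,
    "DLP_mGy_cm": 39.6,
    "filtration_mm_al": 1.4,
    "scan_angle_deg": 360
   }
  },
  {
   "protocol_id": "newtom_standard_12x8",
   "device": "NewTom 5G",
   "modality": "CBCT",
   "kVp": 110,
   "mAs": 3.5,
   "fov": "12x8 cm Standard",
   "extra": {
    "CTDIvol_mGy": 1.16,
    "DLP_mGy_cm": 10.5,
    "filtration_mm_al": 1.4,
    "scan_angle_deg": 360
   }
  },
  {
   "protocol_id": "newtom_standard_15x12",
   "device": "NewTom 5G",
   "modality": "CBCT",
   "kVp": 110,
   "mAs": 2.6,
   "fov": "15x12 cm Standard",
   "extra": {
    "CTDIvol_mGy": 1.15,
    "DLP_mGy_cm": 14.7,
    "filtration_mm_al": 1.4,
    "scan_angle_deg": 360
   }
  },
  {
   "protocol_id": "newtom_standard_18x16",
   "device": "NewTom 5G",
   "modality": "CBCT",
   "kVp": 110,
   "mAs": 2.4,
   "fov": "18x16 cm Standard",
   "extra": {
    "CTDIvol_mGy": 1.14,
    "DLP_mGy_cm": 18.2,
    "filtration_mm_al": 1.4,
    "scan_angle_deg": 360
   }
  },
  {
   "protocol_id": "planmed_verity",
   "device": "Planmed Verity",
   "modality": "CBCT",
   "kVp": 92,
   "mAs": 22.5,
   "fov": "13x16 cm ULD",
   "extra": {
    "filtration_mm_al": 8.1,
    "scan_angle_deg": 210
   }
  }
 ]
}
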