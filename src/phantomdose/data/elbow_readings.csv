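protocol_id,exposure_id,dosimeter_id,layer,location,replicate,absorbed_dose_mGy
shimadzu_radiography,ap_plus_lat,1,17,Humerus,1,0.3
shimadzu_radiography,ap_plus_lat,2,16,Humerus,1,0.5
shimadzu_radiography,ap_plus_lat,3,16,Triceps brachii,1,0.6
shimadzu_radiography,ap_plus_lat,4,16,Bicep brachii,1,1.1
shimadzu_radiography,ap_plus_lat,5,15,Humerus,1,0.5
shimadzu_radiography,ap_plus_lat,6,14,Cubital nodes,1,0.9
shimadzu_radiography,ap_plus_lat,7,14,Ulna,1,0.3
shimadzu_radiography,ap_plus_lat,8,13,Ulna,1,0.4
shimadzu_radiography,ap_plus_lat,9,12,Radius/Flexor carpi ulnaris,1,1.1
shimadzu_radiography,ap_plus_lat,10,12,Ulna,1,0.4
shimadzu_radiography,ap_plus_lat,11,11,Ulna,1,0.4
siemens_msct,scan,1,17,Humerus,1,11.5
siemens_msct,scan,2,16,Humerus,1,17.1
siemens_msct,scan,3,16,Triceps brachii,1,18.8
siemens_msct,scan,4,16,Bicep brachii,1,21.6
siemens_msct,scan,5,15,Humerus,1,16.4
siemens_msct,scan,6,14,Cubital nodes,1,18.5
siemens_msct,scan,7,14,Ulna,1,15.1
siemens_msct,scan,8,13,Ulna,1,14.9
siemens_msct,scan,9,12,Radius/Flexor carpi ulnaris,1,19.3
siemens_msct,scan,10,12,Ulna,1,13.3
siemens_msct,scan,11,11,Ulna,1,11.1
newtom_hires_12x8,scan,1,17,Humerus,1,0.3
newtom_hires_12x8,scan,2,16,Humerus,1,2.9
newtom_hires_12x8,scan,3,16,Triceps brachii,1,1.5
newtom_hires_12x8,scan,4,16,Bicep brachii,1,4.9
newtom_hires_12x8,scan,5,15,Humerus,1,3.3
newtom_hires_12x8,scan,6,14,Cubital nodes,1,4.2
newtom_hires_12x8,scan,7,14,Ulna,1,3.0
newtom_hires_12x8,scan,8,13,Ulna,1,2.6
newtom_hires_12x8,scan,9,12,Radius/Flexor carpi ulnaris,1,0.5
newtom_hires_12x8,scan,10,12,Ulna,1,0.3
newtom_hires_12x8,scan,11,11,Ulna,1,0.6
newtom_standard_12x8,scan,1,17,Humerus,1,0.1
newtom_standard_12x8,scan,2,16,Humerus,1,0.9
newtom_standard_12x8,scan,3,16,Triceps brachii,1,0.5
newtom_standard_12x8,scan,4,16,Bicep brachii,1,1.3
newtom_standard_12x8,scan,5,15,Humerus,1,1.0
newtom_standard_12x8,scan,6,14,Cubital nodes,1,1.3
newtom_standard_12x8,scan,7,14,Ulna,1,1.0
newtom_standard_12x8,scan,8,13,Ulna,1,0.7
newtom_standard_12x8,scan,9,12,Radius/Flexor carpi ulnaris,1,0.2
newtom_standard_12x8,scan,10,12,Ulna,1,0.1
newtom_standard_12x8,scan,11,11,Ulna,1,0.2
newtom_standard_15x12,scan,1,17,Humerus,1,0.5
newtom_standard_15x12,scan,2,16,Humerus,1,0.8
newtom_standard_15x12,scan,3,16,Triceps brachii,1,1.1
newtom_standard_15x12,scan,4,16,Bicep brachii,1,1.1
newtom_standard_15x12,scan,5,15,Humerus,1,0.8
newtom_standard_15x12,scan,6,14,Cubital nodes,1,1.5
newtom_standard_15x12,scan,7,14,Ulna,1,0.9
newtom_standard_15x12,scan,8,13,Ulna,1,1.2
newtom_standard_15x12,scan,9,12,Radius/Flexor carpi ulnaris,1,0.6
newtom_standard_15x12,scan,10,12,Ulna,1,0.9
newtom_standard_15x12,scan,11,11,Ulna,1,1.0
newtom_standard_18x16,scan,1,17,Humerus,1,0.5
newtom_standard_18x16,scan,2,16,Humerus,1,1.0
newtom_standard_18x16,scan,3,16,Triceps brachii,1,1.1
newtom_standard_18x16,scan,4,16,Bicep brachii,1,1.3
newtom_standard_18x16,scan,5,15,Humerus,1,0.8
newtom_standard_18x16,scan,6,14,Cubital nodes,1,1.2
newtom_standard_18x16,scan,7,14,Ulna,1,0.9
newtom_standard_18x16,scan,8,13,Ulna,1,0.5
newtom_standard_18x16,scan,9,12,Radius/Flexor carpi ulnaris,1,1.0
newtom_standard_18x16,scan,10,12,Ulna,1,0.5
newtom_standard_18x16,scan,11,11,Ulna,1,0.3
planmed_verity,scan,1,17,Humerus,1,0.3
planmed_verity,scan,2,16,Humerus,1,1.3
planmed_verity,scan,3,16,Triceps brachii,1,1.4
planmed_verity,scan,4,16,Bicep brachii,1,1.4
planmed_verity,scan,5,15,Humerus,1,1.4
planmed_verity,scan,6,14,Cubital nodes,1,1.3
planmed_verity,scan,7,14,Ulna,1,1.3
planmed_verity,scan,8,13,Ulna,1,1.0
planmed_verity,scan,9,12,Radius/Flexor carpi ulnaris,1,1.1
planmed_verity,scan,10,12,Ulna,1,0.7
planmed_verity,scan,11,11,Ulna,1,0.4
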