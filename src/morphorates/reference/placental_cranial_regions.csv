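region,origin,k_mult,k_mult_sig,allometry_z,allometry_z_sig,disparity,rate
nasal,CNC,0.820,*,4.41,*,0.0055,5.810
premaxilla_d,CNC,0.704,*,4.77,*,0.0045,6.285
premaxilla_v,CNC,0.693,*,3.77,*,0.0029,8.588
maxilla_d,CNC,0.554,*,4.71,*,0.0048,5.416
maxilla_v,CNC,0.565,*,4.04,*,0.0027,4.905
palatine,CNC,0.406,*,2.61,*,0.0011,3.883
jugal,CNC,0.380,*,4.10,*,0.0025,7.021
frontal,CNC,0.473,*,5.24,*,0.0047,6.362
squamosal_v,CNC,0.523,*,5.21,*,0.0015,4.202
squamosal_z,CNC,0.475,*,1.99,,0.0012,5.624
glenoid_fossa,CNC,0.521,*,2.86,*,0.0007,4.219
pterygoid,CNC,0.359,*,2.40,,0.0004,3.877
parietal,PM,0.493,*,5.99,*,0.0034,5.499
supraoccipital,PM,0.499,*,5.76,*,0.0027,4.005
occipital_condyle,PM,0.545,*,4.39,*,0.0008,3.812
basioccipital,PM,0.433,*,3.78,*,0.0006,2.269
basisphenoid,PM,0.328,*,2.72,*,0.0006,2.549
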