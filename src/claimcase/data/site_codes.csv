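pattern,site_group
S22.2-5,RibSternum
S42,ClavicleScapulaHumerus
S49.7,ClavicleScapulaHumerus
S52.5,RadiusUlnaDistal
S52.1-4,RadiusUlnaOther
S52.6-9,RadiusUlnaOther
S59.7,RadiusUlnaOther
S62,HandBone
S69.7,HandBone
S72.0-2,FemurHip
S72.3-9,FemurOther
S79.7,FemurOther
S82.0-4,PatellaTibiaFibula
S82.7,PatellaTibiaFibula
S82.9,PatellaTibiaFibula
S89.7,PatellaTibiaFibula
S82.5-6,Ankle
S82.8,Ankle
S92.4-5,FootToe
S92.0-3,FootOther
S92.6-9,FootOther
S99.7,FootOther
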