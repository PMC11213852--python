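# Default ICD-10 prefix map for the 22 long-term-care-related diseases.
# EDITABLE APPROXIMATION: these are standard chapter-level prefixes, one block
# per disease; replace with your validated code list for real analyses.
# A claim matches a disease when its diagnosis code starts with any prefix.
hemorrhagic_stroke: [I60, I61, I62]
ischemic_stroke: [I63]
other_cerebrovascular: [I65, I66, I67, I68, I69]
ischemic_heart_disease: [I20, I21, I22, I23, I24, I25]
arrhythmia: [I44, I45, I46, I47, I48, I49]
heart_failure: [I50]
other_cardiac: [I30, I31, I33, I34, I35, I36, I37, I38, I40, I41, I42, I51]
cancer: [C]
copd: [J43, J44]
pneumonia: [J12, J13, J14, J15, J16, J17, J18]
other_lrt: [J20, J21, J22, J40, J41, J42, J45, J46, J47]
rheumatoid_arthritis: [M05, M06]
other_arthropathies: [M15, M16, M17, M18, M19, M20, M21, M22, M23, M24, M25]
dorsopathies: [M40, M41, M42, M43, M45, M46, M47, M48, M50, M51, M53, M54]
dementia: [F00, F01, F02, F03, G30]
parkinsons: [G20]
insulin_dependent_diabetes: [E10]
non_insulin_dependent_diabetes: [E11, E12, E13, E14]
visual_impairment: [H25, H26, H40, H54]
hearing_impairment: [H90, H91]
femur_fracture: [S72]
other_fractures: [S02, S12, S22, S32, S42, S52, S62, S82, S92, T08, T10, T12]
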