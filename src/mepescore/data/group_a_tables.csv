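feature,tp,fp,fn,tn,provenance
abutment,45,52,0,3,"reconstructed from derivation-cohort counts: 97 feature-positive, detection 45/97, cohort 100 with 45 pEPE"
interface_gt10,23,8,22,47,"reconstructed from derivation-cohort counts: 31 feature-positive, detection 23/31, cohort 100 with 45 pEPE"
irregular_margin,33,20,12,35,"reconstructed from derivation-cohort counts: 53 feature-positive, detection 33/53, cohort 100 with 45 pEPE"
bulging,31,6,14,49,"reconstructed from derivation-cohort counts: 37 feature-positive, detection 31/37, cohort 100 with 45 pEPE"
nvb_asymmetry,11,2,34,53,"reconstructed from derivation-cohort counts: 13 feature-positive, detection 11/13, cohort 100 with 45 pEPE"
measurable_disease,9,0,36,55,"reconstructed from derivation-cohort counts: 9 feature-positive, detection 9/9, cohort 100 with 45 pEPE"
angle_obliteration,4,0,41,55,"reconstructed from derivation-cohort counts: 4 feature-positive, detection 4/4, cohort 100 with 45 pEPE"
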