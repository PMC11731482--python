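# ICD-9 / ICD-10 prefix lists used to derive binary comorbidity flags.
# version: 1
# Format: condition: comma-separated prefixes; "A-B" denotes an inclusive
# prefix range expanded at load time; dots are stripped before matching.
hypertension: 401-403, 405, I10-I16
atherosclerosis: 414, 437, I25
cerebrovascular: 437, I67.3, I69
diabetes: 249, 250, E09-E11, E13
ischemic_heart_disease: 21.29, 410-414, 429.2, I20-I25, I31.2, I51.3, I51, I82.9, I97, I99.8, Q21, Q89.9, Z13.6
malignant_neoplasm: 140-239, C00-C96, D00-D49, H47
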