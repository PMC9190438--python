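# Published reference values: numbers of increasing and decreasing DEGs per region x sex
# experiment of the rat ketamine infusion time course (adjusted p < 0.01 plus the variable
# expression-ratio threshold). The amygdala increasing count is printed as 992 in the study's
# summary table and 991 in its figure legend; both are recorded here.
region	sex	n_up	n_down	n_up_alt
frontal_cortex	male	314	567
hippocampus	male	1109	370
amygdala	male	992	142	991
hippocampus	female	180	101
amygdala	female	175	105
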