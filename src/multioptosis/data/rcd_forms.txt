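alkaliptosis
anoikis
apoptosis
autophagy
autosis
cellular_senescence
cuproptosis
disulfidptosis
efferocytosis
entosis
erebosis
ferroptosis
immunogenic_cell_death
lysosome_dependent_cell_death
methuosis
mitochondrial_permeability_transition
mitoptosis
mitotic_catastrophe
necroptosis
necrosis
netosis
oxeiptosis
paraptosis
parthanatos
pyroptosis
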