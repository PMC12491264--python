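cell	tumor_role	tic_role
B cells naive	dual	other
B cells memory	dual	other
Plasma cells	dual	other
B cells class-switched memory	dual	other
T cells CD8	anti_tumoral	hot_marker
T cells CD4 naive	dual	other
T cells CD4 memory resting	dual	other
T cells CD4 memory activated	dual	other
T cells CD4 Th1	dual	other
T cells CD4 Th2	dual	other
T cells follicular helper	dual	other
T cells regulatory (Tregs)	pro_tumoral	cold_marker
T cells gamma delta	dual	other
NK cells resting	anti_tumoral	other
NK cells activated	anti_tumoral	hot_marker
Monocytes	dual	other
Macrophages M0	dual	other
Macrophages M1	anti_tumoral	hot_marker
Macrophages M2	pro_tumoral	cold_marker
Dendritic cells resting	dual	other
Dendritic cells activated	dual	other
Mast cells activated	dual	other
Eosinophils	dual	other
Neutrophils	dual	other
Cancer associated fibroblasts	pro_tumoral	other
Common lymphoid progenitor	dual	other
Endothelial cells	dual	other
Granulocyte-monocyte progenitor	dual	other
Hematopoietic stem cell	dual	other
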