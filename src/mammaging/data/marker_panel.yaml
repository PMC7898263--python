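# Canonical mouse mammary marker panel (epithelial, stromal and immune
# lineages).  Used by `mammaging classify` when no panel is supplied.
myoepithelial: [Krt17, Krt14, Krt5, Acta2, Myl9, Mylk, Myh11]
hs: [Prlr, Pgr, Esr1, Cited1, Prom1]
av: [Mfge8, Trf, Csn3, Wfdc18, Ltf, Elf5]
fibroblast: [Col1a1, Col1a2, Col3a1, Fn1, Pdgfra, Pdgfrb]
vascular_endothelial: [Pecam1, Cdh5, Eng, Sox17, Sele]
pericyte: [Rgs5, Des, Notch3]
lymphatic_endothelial: [Mmrn1, Prox1, Flt4, Ccl21a]
dendritic: [Napsa, Traf1, Cd209a, Flt3]
macrophage_Ma: [Csf1r, Fcgr3, Adgre1, Mrc1, Cd209f, Cd163]
macrophage_Mb: [Mmp12, Mmp13, Spic]
nk: [Gzma, Ncr1, Itgae]
t_cell: [Cd3d, Cd3e, Cd3g, Cd8a, Cd8b1]
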