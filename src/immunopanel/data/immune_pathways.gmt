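innate	na	Cd14	Tlr2	Tlr4	Tlr7	Tlr8	Marco	Slc11a1	C3ar1	Cfb	Cfd	Il1a	Il1b	Nlrp3	Casp1	Ccl2	Ccl3	Cxcl1	Cxcl5	Mmp9	Camp
adaptive	na	Cd3d	Cd3e	Cd3g	Cd4	Cd8a	Cd8b1	Ctla4	Icos	Cd28	Cd19	Ms4a1	Tnfrsf17	Ighm	Il21	Il21r	Lag3	Foxp3	Tbx21
B-cell functions	na	Cd19	Ms4a1	Tnfrsf17	Cd79a	Cd79b	Blnk	Btk	Cxcl13	Cxcr5	Ighm	Aicda	Cd40
T-cell functions	na	Cd3d	Cd3e	Cd3g	Cd4	Cd8a	Cd8b1	Ctla4	Icos	Cd28	Txk	Itgal	Ccr2	Cd48	Lag3	Eomes	Foxp3
chemokines & receptors	na	Ccl2	Ccl3	Ccl5	Ccl7	Ccl8	Ccl12	Cxcl1	Cxcl3	Cxcl5	Cxcl9	Cxcl10	Cxcl11	Cxcl13	Cxcl16	Cxcr2	Cxcr3	Cxcr5	Cxcr6	Ccr2
cytokines & receptors	na	Il1a	Il1b	Il1r2	Il1rn	Il6	Il11ra1	Il21	Il21r	Tnf	Lta	Tnfsf11	Tnfrsf11a	Csf3r	Spp1
interferon	na	Irf4	Irf7	Ifit1	Ifit3	Isg15	Mx1	Mx2	Oasl1	Rsad2	Stat1	Stat2	Ifih1	Ifnar1	Ifngr1
complement	na	C1qa	C1qb	C2	C3	C3ar1	C4a	Cfb	Cfd	C6	C7	Serping1
TNF superfamily	na	Tnf	Lta	Tnfsf11	Tnfsf13b	Tnfrsf11a	Tnfrsf17	Cd40	Fas	Faslg
adhesion	na	Itga4	Itgal	Sele	Selplg	Vcam1	Icam1	Cd34	Pecam1
cell cycle	na	Ccnd1	Ccnb1	Cdk1	Cdkn1a	Mki67	Top2a	Vegfr2	Angpt2	Kdr
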