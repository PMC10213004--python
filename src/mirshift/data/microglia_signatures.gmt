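homeostatic	editable_placeholder	P2ry12	Cx3cr1	Hexb	Cst3	Tmem119	Selplg	Siglech	Olfml3	Csf1r	Sparc
DAM	editable_placeholder	Apoe	Lgals3	Apoc1	Cst7	Itgax	Clec7a	Lpl	Spp1	Axl	Ccl6
IRM	editable_placeholder	Ifit1	Ifit3	Irf7	Isg15	Oasl2	Ifitm3	Usp18	Rsad2	Stat1	Cxcl10
CRM	editable_placeholder	Ccl3	Ccl4	Il1b	Tnf	Nfkbia	Ccl2	Socs3	Atf3	Ccrl2	Zfp36
cycling	editable_placeholder	Mki67	Top2a	Mcm2	Birc5	Cenpa	Ccnb1	Cdk1	Ube2c	Tubb5	Stmn1
exAM	editable_placeholder	Fos	Jun	Junb	Egr1	Hspa1a	Hspa1b	Dusp1	Ier2	Ier3	Klf6
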