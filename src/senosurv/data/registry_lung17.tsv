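accession	platform	n
GSE102287	GPL570	66
GSE14814	GPL96	90
GSE157011	GPL570	235
GSE19188	GPL570	156
GSE29013	GPL570	55
GSE30219	GPL570	307
GSE31210	GPL570	246
GSE3141	GPL570	111
GSE31908	GPL570;GPL96	40
GSE37745	GPL570	196
GSE43580	GPL570	150
GSE4573	GPL96	130
GSE50081	GPL570	181
GSE68465	GPL96	462
GSE77803	GPL570	156
GSE8894	GPL570	138
TCGA	RNAseq	133
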