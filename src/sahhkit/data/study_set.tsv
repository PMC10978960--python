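# Study set of biochemically tested SAH/SIH hydrolases: published motif class,
# architecture features, semi-quantitative assay symbols (cleavage/synthesis per
# substrate; - means no conversion) and presence of DadD / MTAN homologues in
# the source genome. Symbols: +++ >70% conversion, ++ 30-70%, + <30%, - none.
enzyme	organism	phylum	motif_class	segment40	cterm	sah_cleavage	sah_synthesis	sih_cleavage	sih_synthesis	dadd	mtan
SacSAHH	Sulfolobus acidocaldarius	Crenarchaeota	HxTxE	absent	short	+++	+++	-	-	no	no
SsoSAHH	Saccharolobus solfataricus	Crenarchaeota	HxTxE	absent	short	+++	+++	-	-	no	no
McSAHH	Methanocella conradii	Euryarchaeota	HxTxE	absent	short	+++	++	-	+	yes	no
MeSAHH	Methanohalobium evestigatum	Euryarchaeota	HxTxE	present	long	+	++	-	-	yes	no
MhSAHH	Methanohalophilus halophilus	Euryarchaeota	HxTxE	present	long	++	++	-	+	yes	no
MiSAHH	Methanocaldococcus infernus	Euryarchaeota	HxExK	absent	short	+	+	++	++	yes	no
MjSIHH	Methanocaldococcus jannaschii	Euryarchaeota	HxExK	absent	short	+	++	++	+++	yes	no
MmaSAHH	Methanococcus maripaludis	Euryarchaeota	HxExK	absent	short	+	++	++	+++	yes	no
MtSAHH	Methanothrix thermoacetophila	Euryarchaeota	HxTxE	absent	short	+++	++	-	+	yes	no
PfuSAHH	Pyrococcus furiosus	Euryarchaeota	HxExK	absent	short	+	+++	++	+++	yes	no
TkSAHH	Thermococcus kodakarensis	Euryarchaeota	HxExK	absent	short	+	++	++	+++	yes	no
CgSAHH	Corynebacterium glutamicum	Actinomycetota	HxTxQ	present	long	+++	+++	-	-	no	yes
PaSAHH	Pseudomonas aeruginosa	Pseudomonadota	HxTxQ	absent	long	+++	+++	+	++	no	no
SaSAHH	Streptomyces albus	Actinomycetota	HxTxQ	present	long	+++	+++	-	+	no	no
SfSAHH	Streptomyces flocculus	Actinomycetota	HxTxQ	present	long	+++	+++	-	+	no	no
TmSAHH	Thermotoga maritima	Thermotogota	HxExK	absent	short	+	++	++	+++	yes	yes
LlSAHH	Lupinus luteus	Plantae	HxTxQ	present	long	+	+++	-	-	no	yes
MmSAHH	Mus musculus	Animalia	HxTxQ	absent	long	+++	+++	+	+++	no	no
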