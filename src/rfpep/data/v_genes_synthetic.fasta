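>IGHV3-23*01|heavy|V
EVQLLESGG.GLVQPGGSLRLSCAASGFTF....SSYAMSWVRQAPGKGLEWVSAISGS..GGSTYYADSVK.GRFTISRDNSKNTLYLQMNSLRAEDTAVYYCAK
>IGHV3-23*02|heavy|V
EVQLLESGG.GLVQPGGSLRLSCAASGFTF....SSYAMSWVRQAPGKGLEWVSAISGS..GGSTYYADSVK.GRFTISRDNSKNTLYLQMNSLRAEDTAVYFCAK
>IGHV3-21*01|heavy|V
QVQLVESGG.GLVKPGGSLRLSCAASGFTF....SSYSMNWVRQAPGKGLEWVSSISSS..SSYIYYADSVK.GRFTISRDNAKNSLYLQMNSLRAEDTAVYYCAR
>IGHV1-69*01|heavy|V
QVQLVQSGA.EVKKPGSSVKVSCKASGGTF....SSYAISWVRQAPGQGLEWMGGIIPI..FGTANYAQKFQ.GRVTITADESTSTAYMELSSLRSEDTAVYYCAR
>IGHV4-59*01|heavy|V
QVQLQESGP.GLVKPSETLSLTCTVSGGSI....SSYYWSWIRQPPGKGLEWIGYIYYS...GSTNYNPSLK.SRVTISVDTSKNQFSLKLSSVTAADTAVYYCAR
>IGHV4-34*01|heavy|V
QVQLQQWGA.GLLKPSETLSLTCAVYGGSF....SGYYWSWIRQPPGKGLEWIGEINHS...GSTNYNPSLK.SRVTISVDTSKNQFSLKLSSVTAADTAVYYCAR
>IGKV3-20*01|kappa|V
EIVLTQSPGTLSLSPGERATLSCRASQSVS.....SSYLAWYQQKPGQAPRLLIYGA.......SSRATGIP...DRFSGSGSGTDFTLTISRLEPEDFAVYYCQQYGSSP
>IGKV3-11*01|kappa|V
EIVLTQSPATLSLSPGERATLSCRASQSV......SSYLAWYQQKPGQAPRLLIYDA.......SNRATGIP...ARFSGSGSGTDFTLTISSLEPEDFAVYYCQQRSNW
>IGKV1-39*01|kappa|V
DIQMTQSPSSLSASVGDRVTITCRASQSI......SSYLNWYQQKPGKAPKLLIYAA.......SSLQSGVP...SRFSGSGSGTDFTLTISSLQPEDFATYYCQQSYSTP
>IGKV1-39*02|kappa|V
DIQMTQSPSSLSASVGDRVTITCRASQSI......SSYLNWYQQKPGKAPKLLIYAA.......SSLQSGVP...SRFSGSGSGTDFTLTISSLQPEDFATYFCQQSYSTP
>IGKV4-1*01|kappa|V
DIVMTQSPDSLAVSLGERATINCKSSQSVLYSSNNKNYLAWYQQKPGQPPKLLIYWA.......STRESGVP...DRFSGSGSGTDFTLTISSLQAEDVAVYYCQQYYSTP
>IGLV1-44*01|lambda|V
QSVLTQPPS.ASGTPGQRVTISCSGSSSNI....GSNTVNWYQQLPGTAPKLLIYSN.......NQRPSGVP...DRFSGSKSGTSASLAISGLQSEDEADYYCAAWDDSL
>IGLV1-44*02|lambda|V
QSVLTQPPS.ASGTPGQRVTISCSGSSSNI....GSNTVNWYQQLPGTAPKLLIYSN.......NQRPSGVP...DRFSGSKSGTSASLAISGLQSEDEADYFCAAWDDSL
>IGLV2-14*01|lambda|V
QSALTQPAS.VSGSPGQSITISCTGTSSDVG...GYNYVSWYQQHPGKAPKLMIYDV.......SNRPSGVS...NRFSGSKSGNTASLTISGLQAEDEADYYCSSYTSSS
>IGLV3-21*01|lambda|V
SYVLTQPPS.VSVAPGQTARITCGGNNIG......SKSVHWYQQKPGQAPVLVVYDD.......SDRPSGIP...ERFSGSNSGNTATLTISRVEAGDEADYYCQVWDSSS
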