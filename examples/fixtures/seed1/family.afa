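>ref01
FPLQCLNNQWF---IMWRRYGVKGPVLLQLVRTDEAVWASRV--D-----RFARAQGL---VFKSE---LEEPGYHQRGAVWEEKDDCNYWYSNKFPEICDYPLFDKPVI--PFRL---ETEPGSKGKKRAGGEREGARAPAK
>ref02
FPIQCLNPQVF--EIMWRRYGVKGPVELQLVRTDEASWASRVGQG-----RFARAQGL---VFLIE---LESPGYHQRGAVWEEK---NYWYFNKFAEICDAPLFLKPVI--PFVP---EGEEGSKGKGRAGGETEGARIPFA
>ref03
FPLQCLNNQGF--PIMWRRYGIKGPVQLQLVRLTEAVWASRV--L-----RFARAQGL---VFNSE---LEDPGYHQRGAVWIEK---NYWYWNKFPEICDAGLFLKPVI--PFVALRFETEEGQKGKKRAGLESEGARAPQK
>ref04
E-IQCLNNQGF--SIMWRRYGRKGPVSLQLVRTEEATWASRV--D-----RFARGQGL---VFAGE---LEGPGAHQRGAVWEEK---NYWGFNKFEEICDEATTL-PVI--PFSL---EGEYGKKGKKRAGGEREGARMPFF
>ref05
EPIQCLNNQGFIKGIMWRRYGRKGPVSLQLVRTEEATWASRV--DFPNSSRFARGQGL---VFMGE---LEGPGAHQRGAVWEEK---NYWGFNKFEEICD-ATFLKPVI--PFVL---EGEYGPKGKLRAGGEREGARMPFF
>ref06
FPIQCLNNQIF--LIMWRRYGWKGPVLLQLVRTDEAVWASRV--T-----RFARRQGL---VFLSE---AEDPGYHQRGAVWEEK---NYWDSNKFPEICDYPLFWKPVI--PFVL---EGEEGSKGKKRAGGEREGAREPFA
>ref07
FPIQCLNPQVF--EIMWRRYGGKGPVELQLVRTDEASWALRV--G-----RFARAQGL---VFLIE---LEKPGYHQRGAVWEEK---NYWYFNKFEEICDAPLFLKPVI--PFVD---EGEQGSKGKGRAGGEREGARIPFA
>ref08
FPLQCLNNQGF--IIMWRRYGIKGPVVLQLVRLTEAVWASRV--L-----RFARAQG-LDHVFKSE---LEDPGYHGRGAVWIEK---NYWYWNKFPEICDDGLFLKPVI--PFVA---ETEEGEKGKKRAGLESEGARAPQK
>ref09
FPIQCLNNQVF--LIMWRRYGWKDPVSLQLVRTDEARWASRV--G-----RFARAQGL---VFLIE---LESPGYHQRGAVWEEK---NYWGFNKFEEICDEPEFLKPVI--PFVL---EGEKGSKGKKRAGGEREGAREPFA
>ref10
FPIQCLNPQVF--EIMWRRYGGKGPVELQLVRTDEASWA--V--G-----RFARAQGL---VFLIEEFHLEKPGYHQRGAVWEEK---NYWYFNKFEEICDAPLFLKPVILQPFVD---EGEQGSKGKGRAGGEREGARIPFA
>paralogA
FPIQCLNNQGFIKEIMWRRYGGKGPVELQLVRTDEAVWASRVGQGFPNSSRFARAQGLLDHVFLIEEFHLEDPGYHQRGAVWEEKDDCNYWYFNKFEEICDAPLFLKPVILQPFVLLRFEGEEGSKGKKRAGGEREGARAPFA
>paralogB
FPIQCLNNQGFIKENMWRRYGGKCPVELQLVRTDEAVWASRVGQGFPNSSRFARAQGLLDHVFLIEEFHLEDPGYHQRGAVWEEKDDCNYWYFNKFEEICDAPLFLKPVILQKFVLLRFEGEEGSKGKKRAGGEREGARAPFA
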