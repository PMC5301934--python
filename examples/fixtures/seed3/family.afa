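>ref01
VSLSAVQHPSPTK--GLRTPSYPDPAQYL-VAWETGIDAQRDP-GVD---NPL-----QSQSFVLVQRVDTGSFLDSCLSITLVHSY-GGLVVFGGPEQGTFVHAESEF-YKPL--SVAIKQRADFHSAVIKDTV
>ref02
VFISAVQHPSITKGIGLRTPSYPWPAQYL-VQWETGIDAERDHAGVD---NSL-----QSQSFVLVQRVDTGSFLDSCLSITLV-SY-GGLVVFGGPEQGTFVQAE--FLYKIR--LVAIKQRADFHSLIIFDTV
>ref03
VSISAVQHPSPTKGIGLRTPSYPCPAQYL-VAWETGIDARRDP-GVD---NTL-----QSQSFVLVQRVDTGSFLDSGLSITLV-SY-RGLVVFGGPEQGTFVAAESEF-YKPL--LVAIKARADFHSRVKKDVV
>ref04
VSISAVQHPSPTKGIGLRTDSYPRPAQYL-VAVETGIDLRRDP-GVD---NPL-----QSQSFVLVQRVDTGSFLDSPLSITLV-SY-RGLVVVGGPEQ-TFMIA--EF-YKPL--LVASKQRSDDHSVVIKDTV
>ref05
VSLSAAQHPSPTKGIGLRTMSYPDPAQDL-VVWETSIDPQRDP-GVD---NPL-----QSISFVLVQRVDTGSFLDSQLSITLV-SY-GGLVVFGDPEQGTFVHAESEF-PKDD--SVAIKQRKDKHSLFIKDLV
>ref06
VSISAVQHPSMTKGIGLETPSWPWPAQYL-VAWETGIDAQRDH-GVDVTKNSL-----RSQSFVLVQRVDFGSFLDSCLSYTLV-SYAGGLVVFTGPEQGTFVHAESEF-YKIR--LVAIKQRADFHSRVDKDTV
>ref07
VSLSAAQHPSPTKGIGACTMSYPDPAQDL-VVWETSIDPTRDP-GVD---NPL-----NSISFVLVQRVDTGSFCDSQLSITLV-SV-MGLVVFYPPEQGAFVHAQSEF-PKDL--DVAIKDRKDKHSSFFKDGV
>ref08
VEISAVQHPSPTKGIGKRTDSYPRPAQYL-VAWETGIDARRDN-GVD---NPL-----QSQSFVLVQRVDTGSFLDSPLSIMLV-SY-IGLVVVGGPEQGTFVHAESEF-YKPL--PVAAKQRSDDHSVVIKDTV
>ref09
VSISAVQHPSPTKGI---TPSYPCPAQYLGVAWETGIDARRDP-GVD---NPL-----QSQSFVLVQRVDTGSFLDSCLS-TLV-SY-RGLVVFGGPEQGTFVHAESEF-YKPLMVLVASKQRLDFHSRVLKDTV
>ref10
VSLSAAQHPSPTKGIGLRTMSYPDPAQDL-VVWETSIDPQRDP-GVD---NFLHPECQQSISFVLVQRVDTGSFLDSQLSITLV-SY-GGLVVFGPPEQGVFVHAESEF-PKDL--SVAIKQRKDKHSSFIKDTV
>paralogA
VSISAVQHPSPTKGIGLRTPSYPDPAQYLGVAWETGIDAQRDPAGVDVTKNPLHPECQQSQSFVLVQRVDTGSFLDSCLSITLVHSYAGGLVVFGGPEQGTFVHAESEFLYKPLMVLVAIKQRADFHSRVIKDTV
>paralogB
VSIGAVQHPSPTKGIGLRTPSYPDPAQYLGVAWETGIDAQRDPAGVDVTKNPLHPECQQSQSFVLVQRVDTGSFLDSCLSIALVHSYAGGLVVFGGPEIGTFVHAESEFLYKPLMVLVAIKQRADFHSRVIKDTV
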