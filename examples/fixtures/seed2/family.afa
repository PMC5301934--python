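>ref01
VDKQTYPLTSNELVLPANTF-KGQGISLSLLDTNWAHQQMYTYLMP--GQPNLALALPILRATTWDDV-KGIPELPRASKKM-GTELEP-SDITEV----------RVKPQ--IPNQLHKVFDAT-YFGEYLSETLS
>ref02
VDKQT-FLTSNEAVWIACTFQKGRGISLSLCATPWAHQQMPTILMP--GQINLALTRPIDRATTWDDV--GIPELPRASKKM-GTE--PVSDIVET----------RVKPQ--IPNQLHGVFDAT-YFGEYLSETLS
>ref03
VDKQTYALTSNEAVLIACTFQKGRGISLSLCATAWAHQQMPTILKP--GQINLALTRPIDRATTWDDV-KGIPELPRASKKM-GTELEPVSDIRET----------RGKPQ--IPNQLHGVFDAT-YFGEYLSETLS
>ref04
VDKQFYALTSNELVSHACTFQKGQGISLSLKATNWNHQQMPTQLMP--GQPNLALTRPIDRATTWDDV-KGIPELPRASKKM-HTEL---SDSVEK----------RVKPQ--IPNQLHKVFDAT-YFGEYLSETLS
>ref05
VDKQTYALTSNELVLIACTFQKGRGISLSLCATPWAHQQMPTILMP--GQINLALTRPIDRATTWDDVAKGIPELPRASKKM-GTELEPVSDIVET----------RVKPQLDIPNQLHKVFDAT-YFGEYLSETLS
>ref06
VDKQTYDLTYNELVLAAKTFQKGDGISLSLCATNWAHQQMPTQLMP--GQPNLAETRPIMRATTWDDV-KGIPGLPRASKKM-STELEPVTDIVKE----------RPKPQ--IPNQLHKVEDAT-YFGENLSETLS
>ref07
VDKQTYDLTANESVGAAFTFQKGEGISLSLPKTMWIHSQMPDLLMPNVGQPSLALTPPIIRATTWDDR-KGIPELPRASIKM-GTELEPVTDPVEK----------RRKPQ--IPNQLHKVSDAT-YFGENLSETLS
>ref08
VDLQTYGRTTNELVLPAGTFQKGQGISLSLSDTNWAHQQMDAPLMP--GRPNLALERPIDRATTWDDV-KGIPELPRASKKM-GTELEPVSDIVMS----------RVKPQ--SPNQLHKVTDAT-YFGEYLSETLS
>ref09
YDKQTYDLTANESVGAAKTFQKGEGISLSLEKTMWIHSQMPDLLMP--GQPSLALTCPIIRATTWDDR-KGIPEWPRADKKMAGTELEPVTDPVEK----------RRKPQ--IPNQLHKVSDAT-YFGENLSETLS
>ref10
VDKQTYALTSNELVLIACTFQKGQGISLSLCATNWAHQQMPTQLMP--GQPNLALTRPIDRATTWDDV-KGIPELPRASKKM-GTELEPVSDIVEKSARQREVIPFRVKPQ--IPNQLHKVFDATQYFGEYLSETLS
>paralogA
VDKQTYALTSNELVLIACTFQKGQGISLSLCATNWAHQQMPTILMPNVGQPNLALTRPIDRATTWDDVAKGIPELPRASKKMAGTELEPVSDIVEKSARQREVIPFRVKPQLDIPNQLHKVFDATQYFGEYLSETLS
>paralogB
VDKQTYALTSNELVLIACTFQKGQGISLSLCATNWAHQQMPTILMPNVGQPNLALTRPIDRATTWDDVAKGIPELPRASKKMAGTELEPVSDIVEKSARQREVIPFAVKPQLDIPNQLHKVFDATQNFGEYHSETLS
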