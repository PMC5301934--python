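>SYN0001_T01 synthetic
RTDTILDQGTGMKNEERRMVETEWPNYSRRERNRVKARINELRESAICEETDGLTWQELQ
AQINQQLMELDLLSIALERIIVIIHLCLVMRVTRSSGLHGNGPNDKIQCELKPHEVFDGH
FLVDKQTYDLTANESVLAAKTFQKGQGISLSLEKTMWAHSQMPTQLMPGQPSLALTPPII
RATTWDDVKGIPELPRASKKMGTELEPVTDPVEKRRKPQIPNQLHKVEDATYFGENLSET
LSSVLNMELVVAPHDDSWLILSRAETLPSPRLFEYAQTFAIHLKVDVAVHRAKQPSEKNA
TKFFPAFGGRNVQGGDFNRGHSWCARLKPRAWWKLGNELVLSETDERG
>SYN0002_T01 synthetic
PAAADSILKEAETHKGRQILIRRARNRVKARINELRELLPSHNAKSDKASILDEAIEYIK
QLQNNNVVAIAISQMCSNGSAESADLRNAGQIEAGVAMVQGPDLGTTSISYILEDRANDQ
RVIIKQSDGAFRVYAKTLISTDLDELGSIEPGAYEDLASAAWLVVRAPAATGRLSPYLTS
NLKPEKPGFDSTTQNATLQDRDWRLPFLCGGEKAAHYRK
>SYN0003_T01 synthetic
QVLDNASGDDSVEYTHAEKEEGTAVKRLVEGLLHGCLSTKYWGDTVPWLLAIVDDALNLT
QPNLADPERRERNRVKARINLLREILPSHNAKSDKAEILDEAIEYIKQLIKPNFGDPRDG
DNGTGPPVRVNAHRHPDPIVAISILHDGTSGQSSAEWGSPTCVTFRATKRSATDEKGPEP
SWIGNPVNKGRPAGELIELPHTDAQMRVLSPLLYHKLPAPAIKMNNAHRKSLMQYADCEA
YDLTLFGKGLKCTYMCVIIGVQGIKIQVATTFYTRDKRMASKFHDIAYDHGLHTEYIYHC
TERTFGMTTLMSEVTFPRPAAFDLRNVLKDVQYVCNLRAPNIDQAHAGFPQQKRPLSYLW
PILPGVIPTSQRRNKVEDGFYLTMF
>SYN0004_T01 synthetic
FCKPIWVSSGRAAAGRAINTMFCLSTPEAAGLDPGSLSGMTAVNYGLQNPTERKVVKIVV
SVVLIAKFRNVQFILLVPGGNCLVVMLHNLPVRDEQYNTGFYTKSPSNQVKRWAGINKVE
GAENAVRCSDLFELTCELWITLKSELALYADNVMWGYESHTAGVSLIVEEAQVDSSELNA
VDDQLSPCKYGETCKYTDCLQSEKKGQLKSGNSHAASSRAGVMKYYFRSTVRAGEPLYFD
AEVPFNPHAQNCLDKRNHSGPRRERNRVKARINELRELLPSHNAKSDKESILDEAIEYIK
QLQGPNNTSYFYQDAFKPTTVTTYRENKQGVGLEVVVFHV
>SYN0005_T01 synthetic
DLASTVSKIPKWLLYGHAVLKVVEDTWLRALCDALNKRCFELSEVIEGSAKGLICEWMVV
NVKGSHGLKWVRVFGHNADFCFDGKLSGITALDATPLSWNKAVSDKFVGDVGDAEKFQTD
A
>SYN0006_T01 synthetic
RPTDQGEITSTFKEFTDVWKNWRSRASQHAIMINIQVAPSALSQIHALSSRLFGEHAKSH
TMSYDKEDRANVKQDRSNVMNASHQLELVPDLVAASNRGMDDMTLAASIEGVLDEAVKKA
GSTKGWGGDLTLSGQELGGRFLITFHRGRYILASINEQLYVNEGLSVTSKNGMIMACPKF
YAVTATRFQVAGDTDDCTEYALDEEMFHTNAGNGCDIPLFEGTCACMAGGKKTGESFDAW
PPCTAQSLEYAGNPEGKYYDTIFKARQFARYDYMFSSINFNEISSPVSNQDAFSYFYSEL
GRIIMGSNAMKVVASPLDVPPWDIAGYISTLSFAECDAADMGYPVRVVIFCWFYRSAVCS
AVAEKED
>SYN0007_T01 synthetic
ANRLMFLPVLYINRDTSDPKEFDVSRERGLAVHQDERQNIPVSSKKVGLFKFTVISSTRF
PGLAAVLLPAPRASLLGAEESPVESQLRERGLPFWDVYSKSPYQDLCLDLSAIAGIAGQL
DKADKEMDSTSRNTDAHYLMGMSMAIIDAQAGNSGAVQSQQADTGPRLANLGKNAIELEK
LEFNPVPMYYLLVISEEGLIECAVSSPMLQKTFLSNRRIKAIVAVTSETYGDEGGAFIRY
AVVYLIFGGGKADKATRFSYSGNRTKGKATQLMWAVGLKGINGFAHLAATACIQPMKIAR
TYGKGRRE
>SYN0008_T01 synthetic
FVNEIKQSSDCPQCLSRTLKPRFRIYGSTSPTAIYLIFGAQARADKCAYVPRDAFLSKIA
EKGKPGWLYLNYIRSFIIDGGSYAPPGSIAAQYMWFETHQNKRQYTRHPGVPESSWYLDD
AERAKQEPPMANDATTVDGEHDLSWSLIHPQIPDASETVEGNGALDMEPSDVQPPGAQIT
FRRRPGVGGTVKAMTVGSSTSPKKQFNCGAACAEDTLAESPG
>SYN0009_T01 synthetic
IGGWSSNTTNKGLEESDGVQNAAAEEDCVWQRGKIQFGDPVPDFNMIADFNRSSFTEGFG
IQEENKYACLDRLLNQLGQDGNIRRRNGKQVTPRAKVQQTGAPKICERVANGPFVIPKQQ
GAAGRLLAGLQRIRAKPTVRQKLGVIFSLKVACMATW
>SYN0010_T01 synthetic
GTLMKVGVHFYCDNVTRAASSYIMGCQQANTSGAFDILLDHFTSVISEIIGEVKREQQVG
VTEKIYQDLSARQREVIPFAANVQAAYKTRRTIGAYCTANTNNLCWQVTFSLENYAPKLQ
EADI
>SYN0011_T01 synthetic
LSGDNRLAKQITFQIDGDMTRPANSGLKLCLGLAGDRVRIKNEATLRKGANLADVRFIPT
DPNQDIPGMKLTRDPAHRSYGLPSTGEFSAFTWKSIGMDLPWTFKAAYEIRFKDSHEGNK
GGHLIQHCAIYKIALAFEHEEALGTSLVGATWAIAPSCRLEFEELAVIKRAEQPLRPQTR
TKSRALVKIISIEQYNADGRVSDQSLFLKIAGRGPKFRVRRK
>SYN0012_T01 synthetic
TYNRDAPIGNAMQRAASTTLHSIVLAAVGEAHVASISTVERDEFYVREDRLSQILSLAKR
NSRNRFEDKKGSFAKIAKLVPFWTVIFTSPCKDVGTRLRGASKAKQSSEAVLFDTCSQET
VCLLKWKQVTNVKRAIGNADLWVLERGFLADSGDLEYLQVLQKTLKVKGTNPLLTCVNRY
RASSVGSSNSFKNVRATRSSQNDLTWEQGNHENIKTPFGLASRACALFLLTLAGSSSREG
HFNGRAQFSVMAARFLSSYPILLIYTIVYLNLLSRAANGSAGNRILIGIQNCNTISRLCM
GY
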