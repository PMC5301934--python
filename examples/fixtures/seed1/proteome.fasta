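>SYN0001_T01 synthetic
LLRDSQSESECTTTLGAPRTGFPSWDLVKNAQVSTPFSESASEIGQEIAGKDPIRPKTPS
HLEYFGAGSQDIKPKNTRIKIDEGGGNYSSRNVQLALEDLSGSLDWKGTDREIFTIYPQL
GRRERNRVKSRINELREIVEYRIPIILALYGRKEVAGYGTNSPISAKILDFMISNTRNGS
FAWLSLNAEQNEVELDRGDAEELKWVSQTVADICNGGGDRPNAKQEIACFKLTGASACWR
HDIHTKCVPDDL
>SYN0002_T01 synthetic
AACGNSGGSRDSSEPEFLLLLESGVLGELIPRRSRNRVKDRINELRELLPSHNAKSDKAS
ILDEAIEYIKILQLATASSVPEKKPIQEILKDWQTIVSYELINFDLPIYKGSLGGVWPGR
FGLKIYENACEYRTAQKKQGLGILEGKLSPMTEDIDMNDRMKVTFEVERGIMVAERIGWG
RWSRRSGPSTVVDIKVKGAGSAEGLITEMSVTDSQKAERCGGRICIHRGQLTRKLLTDKL
KNLKQHNRDHVWYASVVRQRNSLFCVRESGPIFEAAACTLDLLLEKTILVFRLSILITVP
YRSVGYILESHQFIIFASVFEHCPIMVTVVNLADLTKAEREEGNTFNLKNSFLDLSYLGN
IDLSVYIFDKSFTREPSVESSFGWIGRD
>SYN0003_T01 synthetic
TTLQTIRRCDRQESSHHDKDLPNAPRDNSEVYRTGPVASFSPSKKVAEYVDYGVVAAHVS
ITGHEWSLGWIEKRSDVQATYRRERNRVKARINELRELLPSHNAKSDKASIATEAIEYIK
QLQTALNTLAVVLATRYAKGDRHADSNFQDQPALRRQTRVKAEGADLGGRTTIRTEEPGE
IAKAFFHDLQHVTGASFHNYGLPQENLPDD
>SYN0004_T01 synthetic
YTYVQGPHSDLTKNDGVPILSSSGFPLMFGRIRAVELVGFYVLANFFVPKAITGGNFMSG
LNIFDMVATWLYQLLLQFRLQVFKGAPPYNIVAGREITHFVATGELLWRLMGYITPVIKI
SVSKSRLEFQEMSPNGDAAFMKEGLSPALETTMRQSGFRWFMLIRDIKVQRYFNDEQSPN
SWVSKSFVGYGGHLEGTVEKKSPKSNESLTPERNLKPALVEDKLILQSAIPAVPLKDAQV
SAALNNTVYHLYQAVPEHNPKRLYRRERNRVKARINEQRELLPSHNAKSDKASILDEAIE
YIKQLQTDDTNY
>SYN0005_T01 synthetic
EASCPMRVFLRECDVSEAPGFELHVMVVVLNLAVEMQSLPSPQTALAEATHLSQVLQTDL
CMGTLETKAGIADGHKGGLIRSAEDIIRRTQNYPIGAVRITSLWVKKEDIFARWQVTPLI
LGELPNRHAEGMIPFLAQTTTEYMECAPPSPLERAPEEVVRFLHDFAYFIFPMSAENNSC
IKLIRDAGCI
>SYN0006_T01 synthetic
NCLMMASRGLRTFSKVTIILWDMPRANKHYDQEVLKFLTAPDFTARALPDSFLFSFGAVA
GPHNITEADLNTWKSKIDTHPLYGMSESMDYKLSWFDRQKPVTMVVSDMNTLNRCAADGA
NNKALDASVAPANPNYNEVGLKSCIKNVGHQELGPNQKFANFAIGQGIRQENVVTGWEKD
MRQAYGRVSLLDISQPQIYHEQEYNDANAAKKSDTKTEAKFLSTCGGELAEAKVETGRTN
RP
>SYN0007_T01 synthetic
SKGELFFTQLTLIQNEGMFVATYPESKRGFVAASSGIQNPKYDPEHGSNHLLLFILCANE
SAFPDKGGFYGDVERPRSEAKKFSDLLASILEIKNAKLVNQKLYKYNVNSSIHVHSELIG
FWQLNTQDEVMNEDFGMIQKLVAPRETDSEKINPASLVEKWPLLVAYLSLSDKSYLARPD
ELEVYRTHDRSQEAMDGLFVGMYQIREDAQPQQNVLDFKNIKGRTHSEYIPNCNALLVEA
PGMGQDLSVHMVDSRWLKLIAMILQIESVFNIQAVTDPHETRNPTHLFKEHPGPSPLIAS
WFQNSQEDHENCQSATSAMALCNACYSQSEDGSRRKLRNFLVWADALVLHTFMTTDGKSQ
LIG
>SYN0008_T01 synthetic
NSIGADDKSKDEVPGTVLKIITRVADLNKLVMGLGPNQYLALLSVETENATKFVCILGIT
EMEPFGLFRFTQDLAEGQPLEGQLGAAVKVFNGTFLWRMILADGAFKTVALQREAFGEFP
FEGKELVSRVVMQILVLKPLCIDVRKADGLDIEDDDSEDSWRADDDLASKECMSNFSLNV
QDQGSMLDAYAALVLYRSSVYHQLYNKARAPGQYIMMERQSFAIDGAKIHIAKPGMSLVS
MCLAWAEETVRTGVDGTQVTEKYQSCVMENVLYVLWSGDALRDEYSGVLGHGQINPLKIF
CQARRSPVILGAKLLAEGKEIGDTNYNPISLSLRPICFKLFGGMCKQTLVRSDLAQGTDA
IEMKAFEEYNSIEHQKAMLQA
>SYN0009_T01 synthetic
LIGTGGVLADRGGGYLVSSSGSLEGLLYPPAAGKVARPFVITGMSTIEPPANVFPVISVA
GFVNDIGYTTDIKGTKSNKCTLALAGVHHGNLITLTKIEANIDLRPAIQIKSEESVEASM
FAMEVVRYGDPFQAHPVCKVAKRLTKGALYVAAATIGRHIQVEEEVMSETGPFLREWTQR
GCGDHSEASVKFTAHSRSLQGTSVSREMAVSLTTIQDASFKLVSMSFCGNHYMMRLEEKG
EISTGEAAIELDPMVSDLIAMYDAEKGQGTDEYARCEPSPYYDLLEPTRSGMESVLLRVC
RVEGLNLNIKGPVYIAPVVQICLPRPSDLKLLNDAKNKLKSSEPLACSRENVLNQLTGFD
K
>SYN0010_T01 synthetic
HLELLGSLNVTPAPGFNERSDEVASRQAVETLGEAFDAPYLSYCKKFRMEVDARKPACGH
LGFVDLFSPPKLYKPCLRLRPDLACQFALQGEFAALFKVSSVQKARDGGVTGILAAMLPT
DVEVEIREDGHTFQTAGVNELKTSGYAVCMKSLGRIKSILSSQRCLNDTQDDDDNDKGPR
PNMSLFDNSRQSCTAMKDNDARVKSVRKVFFQSGGACHCASTDHAKDMQRDSTGYHGEWY
SGESSQACNASYYSADYLDADTGRVIVTDDVTSQWKSSKGDVSRFSEPEKNRVWSAIRTA
IVVTEGVVWQRFRGTNGDDEVIMDVYLVYQDPEVVEIQFTLPKSSSIIFVDIAPWLAIPE
LHASGEPKG
>SYN0011_T01 synthetic
YNKNKSTGVGPVQAPTAEKIYCEPDPPMKLIIHGEMNLLSVAKLDHKAKDKEDALAIAQP
EIRDSPVNAKQLIFQESGNVNTCLPEQPLSAVCSEANMRTLLNHSSEQFGNKNFRDAELT
HCYQGFDDRDQKPIDATSDGKVIMAARLAREVYVENTPAGQIEMTQGEDGNVGRVISYFM
TDAPNVPVLPSKKQALDLAALGQMLTAVCAWELIGLTKPWKGLSQWHVIAPVFVTGSGPL
EKKCTGGVI
>SYN0012_T01 synthetic
ITHVLIGGYLAASVWAFSSSESRVKPERATQGELRVWLGDRNFLISCEELHNLHQNDINP
LESLPTADRDAYATYIPDYVGASYDVTEEEGKEGNNYEVFETNQVSRHGLIERSVPLIKS
RDNVTISTPTDVTKSLSGPAYRVPQVYI
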