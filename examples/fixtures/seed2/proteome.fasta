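>SYN0001_T01 synthetic
LQHLFDAQKVTIYNSKEEENDATDKLPLVRNPLWFQMAGVSAGASDAYKGAIILADEKGN
GVWAEMSAEKQVTSAYPCGPIKSSLSKYRRERNRVKARINELRENWATMREMGDAVQEGL
SDWVFPIQCLNPQVFEIMWRRYGGKGPVELQLVRTDEASWASRVGRFARAQGLVFLIELE
SPGYHQRGAVWEEKNYWYFNKFAEICDAPLFLKPVIPFVPEGEEGSKGKGRAGGEREGAR
IPFAGSTITALGKFVGVDKKRHLAGRDLFEDSQIIRNVVLPLGKRMPLVSDSVSHIFALT
SPTPFSITHCRDTKSALQDNDGIPDESRKGQLGTESPPQRTVGEVEFSWTLIYRP
>SYN0002_T01 synthetic
SRVERNRVKARINELRELLPSHNAKSDKDSILDEAIEYIKQLQIGAQNTERSSRKAPACK
DKTESYAKQRGSIELNTPCNHQAPSAAVVEVKLLHTNVPVLLNASDVAQSLCSGGQYCKQ
GVNAEDKVDEENKKDSLTALITQLEQVSWNGFSSPSLTQFNPEVS
>SYN0003_T01 synthetic
SQHLFNEKTPNDSPVVVLSDASQVGLSNTITTVIVGNYPNILLQLGEYPRVERNRVKARI
NELRELLPSHNAKSDKASILDEAIEYIKQLQEHPFVLQPEVTDMLGIGPKDFEPMILPFA
WEFQYDKTCFNSDKNLLYYEGKDDMYGEPGACTDPKSLFEFFFGNLAKVVGEGDGVTKMQ
QQRNDQQEEPISGPPDGIGCFLFPKKESAVNVMIIVLIEEKKSDKDGLTDEQLCQWRYRH
SMCIVPIQQELSDMDGSISRPDKTPALLLKSLTVVSAAELGDVKELYRVDRHIKLSGLKP
MATPELVTKFVRPKTESSLIQIKGSELKYDMFVDVPEKGLSLYVFDQIGVNGMMSKLETV
ARYTSFYITSNWWKLVKTFGIGKF
>SYN0004_T01 synthetic
GTRAAKAVYNGEDMEFRTPWSRRERNRVKARINELRELLPSTNAKSDKASILDEAIEYIK
QLQKIESLTLTRNRRASDLLSFQSHNKRTLAVNERKEHNHDAIRHKSPYTVLSYALRFAL
AEARAVMKDIGTLAVYYGLRDKGTAVAVKEGVESTGNLVEIPDGSPMTFV
>SYN0005_T01 synthetic
VRRNSGRDPYWFVNKIKKVRESNYGRLFDVAGLGMESNPYELEGLRESRLTKYWKWSLNS
WVWKADICLDGGVLDRVRATESSQAIDSAKRSKCTGLAGVRRMDFVDPIRDDLGSYDFEI
FNILTTEGNLARSKDQAANKYFEGTQADVMKAFATVLSDGPQNC
>SYN0006_T01 synthetic
VFQTDLPYQKQLDFPQKGARERVSNAQYGTLSRGLCDGRITPVSKDLLDDYSIAGMWARW
WNSQAGVDEPVINYTAQDWRVLAECRTKTFKKLAEDPLYPEDQSDLWVDLTNAIGHYSYS
YKVLSETIVGILTRGLTTRHVIRSQAESPTQQTVGTWDKLMTAASGLDWLAVNGCATDFM
ARPPIGSYNVESFGAVEFHKSCAFTSVLANG
>SYN0007_T01 synthetic
GRNRPNMSQQHFSPSGASERACDDSAGMLQLDCSGDGDSENKNVLDQGGSFGKSSIAADY
KLQLEREHAPSHAIEEPPNKNLICTITTKPLSYATFEQFLDALEVADVGPAQLSQPLNSI
QDTNEFHALLMKERKARANLVVINDLGKIVNTKHWGAFRKSQVETEKVHNIDLAAKHSLH
GTSMDLADIAALSFTDKISMMCEGQTVTSTPADAQQEGDTSQNLKDLNPCVQPFLPEPNS
LQVPAAIKNKKASLVVWPAKLFARSEARQDEFPTSEGLPFINPRLAFMGYFTESQYQVTI
MDETEHESENETDNWQMRKDRTFLTGGHDVPQSTLWAFENRTYVLLLALQAGDDHKDPPY
RA
>SYN0008_T01 synthetic
DVEELSLAIWFQGAILTETDGKWIHAFPRKVAPILGDDCMYDTPGDEYNYGDMCLLVQAA
AMNMTELTQIACWDASMKPFIGEQIINPSQGCNEITAIELLGVMDSQISRHVPAEAPDLL
AYVYIGDYSDASGISSLTLKPLGRQEMLMMQKLVARA
>SYN0009_T01 synthetic
TDASHKNLRKSHDSVTCLPNSYPTILVFMPGRRNEFMFRRCPQPSQEGQSFKDRSASGIK
VISYQQQMAIIEQEECHKVCRFTIPPSTMLIKVGNISIEKLEAGASHQTLTLALIILTSS
ERRFVITLLQSGQDFIATLEPGEIFFVALL
>SYN0010_T01 synthetic
LWASACKLLGYTNVGTKAVFDERRTFEVFDSEPGQISFAIAFFFEGQASDSRLKAVPFEV
NSSATPLLLTGAEQIKVLAIKYDRSDVGAVYLFAVLYNSKINAKPFEHGRDTDFLGGAAT
YVLEK
>SYN0011_T01 synthetic
LPKSTRPWPAYVEEVLSSTITMIKVHVQHCTCVGVAATEELLETCDYLADGITIIKHKVT
MDRHTQMGNVRIPGGQTRGFSFRSAYYEIVGKDTKVYLHASYASFKIMHVANQWNKEGSA
TTLSGERRHQDASLRLLVVLHHSGLAFTVYFNMTKVGKEDQSKSNSKGQFSSFQLTAEGS
FGLSSAKVKEDKPWTVEDHQLTM
>SYN0012_T01 synthetic
YPIKSLKESLDLQSVEMGINQADSIALKGVSLSVGDINVRQKQHAELIVRSGQERDEALM
VGGFRGQNKHSVGNVFCSKQWHPKVIKRGTGRTAKLTLRFLQDDCEFHLDHFPNSSGQIK
QKTAVLPCIATHYTFAEAVETDLAGFKQWVIRQYIQKYLRDVRESEPVLNSDDEYTSNRL
TTEKPTFVTFRVVTDVKDAQLLFPRLDANEASAKREEHHCMYVRGTALQSVPNSVESSLT
TDWLDIYIWLGTGQAEMGAIPRTCSLRIIVPNSITQSVQQSPTKGGVGDKNRDLS
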