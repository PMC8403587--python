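>APH07629
PELTLQLLEEHNNIVADALIGSPLEDWAPSSIPLNAVACTPPTWKGRLEYGRTDDWAEVVFLIAGIILGQ
DACIGPAGPPAHVVMSQGSTNKLNYAINKKIKRQGPGPRQGTAGWGLIRKSSWYDFLHGVSARLFEQTGS
DRLRKTPQMESRTHRMKENQLCAVLKYHEPIYGGNKIDVIIATVANKALSLWMLPEGFGFTFDLGKCRPL
QCVGSDGVAKECLNQLPWGDTAGVCDVNLGPAALTGKIYGDVSQCQYEARVVNGVKAFARRTQAMMQPII
VNIVPCGALPKTRLGTFAVEKEGGSRWARMPVSIAAGRKPNGGAPLKIALAHKPQEVSESSGENQDLSIE
HRIYDLITWAGREGAFNNGDVDLRRETQVLCRNDLAVSRVVVGTCPRGARVYHAQSIYLVQVWEFKGFVI
LFALLANLTSTIPKLEVIKAAELYVLYFFGAVMDVFHTEMEYLQIHDYSDYLFRVVAAPRASVPPYAYFY
GGTPLTYVNGVHGMANHTVGTMETGSLDVDEGGKFEVEDYEAYTGSFIIFSNARQRTRTILILTHLALGS
FISFTVAPDLNEVPSEEDVDALMVRFSILFYLVYNVSKSRTSTDNLEIGWSCDTSKTGISDPCGEQEVVK
SALCAGETQCYAASIIIPETPKNQTPWYPMEETVCNDDLADTDKQTKGVRPPYDHYIEKTYHGFRCLLTS
LVAIVATQSVPCFIGKRYLLEGENNGTDPFISEGGYMNELLYDLRCPQAFSELSCNVVDLLEDAISSVNA
ILVITEVPTLKKTQPQPATPGIYSAVVPGNTTDFLPIYIVIVACLYTPMEIKLPQGRRRMITVGECVKTG
GNIGESKFYNAVIASVAKDALAKNALKAVLRLSNDAEPFVDQYDPGFAVSNNPRAARKCTSNPQQSRSAK
VHKDMDGSYIGANGFEGLEVAHYSVDKDTKEFTRDLRTKKNQMMIRPVSALPMARSVAYVAIEKTGQCTV
DAGLKVATDSYEEKRRYPRVDPGGQVTGTQIRGPILKPQNNGGSAKQNESNPHTDCIGAQLSVKGQDREV
SVEEKDFLKRPQAKRTIKFNFGYISDMITEGWYTRILGSAQISAGCELSLNLRGKAFIVQVVDKHKHRYD
YDGGEEEYLKPVGLAATEDRSGFSYHNRVARRLSSVSAYTVPDTEQGVHAGGDLRPQQDPEDRTSGFSNR
DVNTFVYKQYRQKQNKSTYSSDNGNKNIEGSFWNCGSPQIMCHNLKIFAFNQPSPEICVNYPEELNYFER
DSCKEILNAVAKRFHAMELLNAMCLEVESNIISKSDPAAT
>XP_960427
GNVLAEARAADAMIPYPEFPAHAEKVAQLSKAVNTVRPATTHNIHAWFREEFVSLKHYVVNANWLNISQA
ETKVKYGVPPILADESGQDMADPPFEVVTQVTSNGMTAPTGAGYLAETPGVEKFFLRSSMYSRPASPMCF
TLGLIMGHSQITRSEKVGCTTNFDQLLHTYESGSGAAACWHTYKRIDAVPVLDPISPGVLTMCRQSYAVT
PEKRFTARSKPGPSYPLISGNVGSGDLTPGTVDYLPFLYTSEDLARTKLFQRAIGSALHVKRILILELNY
VVSTDLFVESQIPNLMFVNVKSKFYLDGKAIATASPEKAEVQPMFSSNHRDTNQCQQQAGIRVSIVIFIK
LMGHVEGWLL
>S3DQP3
NNSPDTEHESYPSNPEDDIEVKQLVLSKGSAIAPVPSDKGECQVSLARSNPDDDSPHSIDASIHKDEWII
IALKEVEQVAPPGKWDKIVTHEAGSNGAKMRCGGAVSTLVRQLGEGPYTPQLLSVIKYNIMATNFVTEYG
HEVIGTWSTERVTLELFRYQLRYQFDESSSGITALILDLLFYRAPLVLCTLACRSIYSLELKGPAESMKA
GNHGQMLQGGITIELRGQDLESTHRLFPLIGRTYENHVDDQAGAKKRRLLVVVDVLKGAAMFQSETLLPD
REQIGQIRGLTVERGIPRPECSKFHTLKKPHGKSLEMTLWLKYWLPTNPCSLHTTVGQQKNTNFLERLLS
KTHGLRWKYTVNTEAIARAPNWYFDPDFFH
>AHY23922
RAVDKNGVLIKDQATYRKLNNWLVVPGIKVVVEAKQPLERDTKALSTINVYTCGNDKEFRLPSLEAMARS
VLKEILWKSKKGDGDILDNKQNFAIKLEAYEPLSKSGMNKFDKAEWQEQLGGPLAVKFYGFRNCKHCCAP
DDIQEDLKGSYMLFFWAYEIPASCMEPGMRDVSVPEEEEIRDAMAMNNFSPHKFVIVTRDRKSWQIGPML
NAYFQDMDEAIGGRQLQDALLLGASLATTLNQPGSQRKSEMSNTKRIPRNNESIHDSNAGIPKYACNGEG
SDGVGIITLLFIQADVNAEEFVPVEAIPGP
>AWM95795
RCVDRNGVLIKDQATLRKLNNWSVVPGIKVKVEAKAPLERDTKALSIIGVYTVGNDFVFRAPSLEAMINS
CLKEICWKSKKGGGDIADNKQNFAIKLEAYEPLCKSGMNKFDDAEHSEQMGGPLAVKFYGLRNAKHCCAP
DDIQEDLPGSCMLFFWAYEITDSCMEPGMIDVSVLEEEEIRDAMAKNNFSGHKFMIVTRDWKSWKIQFCV
NAYEQDEDEWIGGRQLQVALMLGASLATTPNQPGTQNRSEMTNTKRQDRNNHVPAVPWLNLEQAGDGGKV
RMWGVSQAEINGEEVQVFVVTCQFHEVETK
>Q6WP50
RAVDKCGVLIKCQATQRKWANWLIVPNIKVVEEANQPYEIDTKAISTINVYTYPQDKEERFPCLEAMARS
YLKEIIWRKKKCDNDVLDNKQNFAIFLEMFEPLSHSGMNKFSKASWQEQLGGFFGVKFYGFRNGKHCCAT
MDKAEDLKGSYMVFLCPIGIPASCMEPDMRDVSVPEEELVRDAMWTTNFSPHKFVIVTRDRKSWQLAPML
NPYHGNMQEAFAGRQLQDALLFGNSLAYTLNQPGSQRKSWMSNTKRIPRSQILAQGNYNQATVIYDNLSC
QKTSGGDYSIRAKGGSLVQEGFVYNLVIQT
>QOE88883
RIVDKHPILIKDQATYYKLDLWLYVPGILVVVEAPQPLERDTGAGSTISVYTCGNDKHFTMPSLEAMAKS
ILEEIIWKHKKGEGDFLKDQSNYAIYSEAYEPLSKNAMNRFNYAEWVERLGGELAAKFYPFNNPKGCTAI
DDDGEDLDGSYMLNFWTNAVPAIDMEPGMRFGIMPERKQIRTQMAMNQHSPHKFVHVTRDRHSWQDGPML
NAYFQDMDEAIGERQLQDRLLLGAALAHFINHPWSQRKSEMSNDKRIPRNSMDKGVFAAAAFEMGIRLQN
SEQTKVLADFMDVEAVFGIKFWNFAIQIGR
>C9K2Q3
RAVDKNGVLWKDQATYRTLSKILVVPGIKDNVEYKQRLERSTKAFSTINVYTCGNDKWFKLPILEAMARS
FLMEALWRSKEGDGDEFDNKQNCAIKLRAYEPLKKSQFTKFMKTEWQEQLGGLLRVKFYGFRVMPHCCAP
DDIQEDLKGSYMLFFWAYEIPASCMGPMMRDFADPEEEMKRDAMAMNNFSPKKFVIVQRDKKSWQIGPML
NASFQMHDYAIGQRQLQDALLLGASMATTLDQPGSQEKSEMSNTKRIPRNPPEIKQSTGMKYWINLTTKL
FNFLFLPRACHLTHVCLEVAALMSHSPVPL
>A0A1B4XBG5
RAMDKNFTLIKDQAWYRKLNQWFVVTGIKVKVDSKQKLDHDTKALSTINVYTYGNDKEFRLPDLEAMARS
VLKRIYGPLKMGDGKYLDNKQNFAIKLEAYEPWSKSHMNPFDKAEWQEQKGKGLAVKFYGFRNCSHCEAP
DNTQEDLKRSYMLFPWAYDIPPLCRCPGTIDVSVRNEEYIGDAMAMNNFIPHKFVICRRKRTSWQTGPML
NAYFDPMDEAIGGRQLHDALLLGKSLRTTLNQPGSQVKGTRSKVKCINRNNEKQFDMSESDLFHRLKPHD
PNEAMLNDMVLVWISGEGCQTAGQPFGIDD
>B2DBF1
RASDKNGILAKDYPFYRKLNNWLVVPGIKVIVEAKQPLERDTKALSTINVYTFSNDKEFRLPSLEAMARY
VIKEILWESKKGDGNICDNKFHFAMKLEAYEPMSKSGMNKFDKAECQEQLGGPLAVTFYEWRNCKHCCAP
DDIQHQLTGSYMLFFWTYEIPMSCMSPGMRDVSVPEDEEIRDAMAMNNFSPHIFVIVTRHRKSWQIGPML
NAYFQMNDEAVGGRQLQDALLLGHVLATNLNQPGSQRKSEMSNTKESPRNYGLLATEPYLLAQLSLIAKD
SMQSHLLRDVRQDCKDGVLSTDQATYNKLNNWMAVWGIKNVVEKKIPLERDTKILSTISKYYCGNQGEFQ
LDSLEAMARSVIKHALKYSKKWDGDIFDNKQNIEAYAEHYEPLSKSGMNKFDQAEWQAQLGGQCAVKLFG
FRNCIHACFIDDIQEEFKGSYIIYKWAYEIPESCMEPGLRDVSVPSEEEIRDKMMMNNLSYNKFVIMVRD
RFLAQIGVMLNNYFTDMDEKTGGRQPQRILTLGDSLATTMTQPGSQRDSEMENTKRIDRN
>P38604
VPGANKRRGVLEDVENGLVKRLDHDVDPTMVLTFIYKMTTSYINDAQEKGGGLLQLPGEHSSVEQASCND
YAAHVYDAKLWLESFISDKQFFQEIDFMSAGFTLAVLKADPSILAGTKHGQTEVAPVYKTTLGGAEIETT
RWTATKSTRLISNIHEGIGAAGGPDVYGNENLVSRSNQEFGLPGAYTAGVYCHPYLGDAEPALWSEQLLC
GKENHGKVVNATTPFEMLKPMINEGTQMKHHGDAVEIVVREDMLAFLHSEQLNEEEPVLVESSGWEQHEI
LGRTSGDLLDPDEKHQKITHACNKNETSHVVWGPLSSYHISPLMEYIAERMNPAVGGILIPPASCTKLIL
VAGWGFGSYQRPADTPQDPIRTRDNGAADV
>QOV03404
DGDMYEMNGRKSSLLQQAKEIQRFARATADLQDSHGKGCNDRSAPESQARLMCMMKDFSPISAMYLVQMD
QSIPERFANRNPLRTPMSFACTLPDTKRYTHVQSTVNGKVTTRPIKNRECAVIADDEVPYAIGILITELL
RSRVTYIMPAVFSEGTQFIDFEMDAALNGFPNGFKRPLLEAPEPLTGEALGEAGPDSTAPYHLEERLNKL
SKVNPFIPIFCNLMPEYLLEHATFFIAYFQSFGIIIEGGRPLSAAALGPSWQDADWRLRFEYGTQSAENA
YDFIRNADIALGFPVVDHIEIADFTVSFSGQTSKVKIVSDYDLANANDNNEPLTDCPVELTSLRLKPALR
LLDINALLRQDDDGSNATGD
>D4D449
WEHKGSREELRRPAAKQFARSNGNKIVTSFYLKSMGKSDSFIIVTLRYGKESVRGNEAKDISAFPTAPYR
NLHTEMNHRSTIAADLIFPTGLGSFPEYSVNSSVLMADVKQYTLTRDPNGLACKDELNGGTGATQPRDSV
GPSNDLGNPFENAINYTEQWLPDSSIEYTVQESIDEAIFVGLRDQRVCALDARGQDGLHPGFGQLIHSLD
QDSCQICDVNVLEYKRSATLRVDRNVERCRDSMHTALSYISSGPHAANFPNYALGEYAKDAASRMEVGIC
NTYGNRIDVHAVTRALHFPVGDLLLHINGDMQKSFATQGYMIHFFAPIDTGIPWWKTGPF
>AMR44282
LTPPTYELISEFRSQRSSVDVLIAPLASELASRESPIDKDLSGKNAHVWGPCINGNDGQD
>OphMA
TLYKIPPLLYMDPSLAARFHGGNVLMQRSPGLVAAFTDWKDHQEEQSCRYVRILPGELRTQERSIRSADS
>ACB30126
RFVAPNKLMKIHAMPSNFLMKVNSKGSSGVDYSLQSTWRMRDEFWAFLALTSTSQAPWAAHEYG
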