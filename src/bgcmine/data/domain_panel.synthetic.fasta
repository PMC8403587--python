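>A
NNSPDTEHESYPSNPEDDIEVKQLVLSKGSAIAPVPSDKGECQVSLARSNPDDDSPHSIDASIHKDEWII
IALKEVEQVAPPGKWDKIVTHEAGSNGAKMRCGGAVSTLVRQLGEGPYTPQLLSVIKYNIMATNFVTEYG
HEVIGTWSTERVTLELFRYQLRYQFDESSSGITALILDLLFYRAPLVLCTLACRSIYSLELKGPAESMKA
GNHGQMLQGGITIELRGQDLESTHRLFPLIGRTYENHVDDQAGAKKRRLLVVVDVLKGAAMFQSETLLPD
REQIGQIRGLTVERGIPRPECSKFHTLKKPHGKSLEMTLW
>ACP
GANGFEGLEVAHYSVDKDTKEFTRDLRTKKNQMMIRPVSALPMARSVAYVAIEKTGQCTVDAGLKVATDS
>AT
ASVPPYAYFYGGTPLTYVNGVHGMANHTVGTMETGSLDVDEGGKFEVEDYEAYTGSFIIFSNARQRTRTI
LILTHLALGSFISFTVAPDLNEVPSEEDVDALMVRFSILFYLVYNVSKSRTSTDNLEIGWSCDTSKTGIS
DPCGEQEVVKSALCAGETQCYAASIIIPETPKNQTPWYPMEETVCNDDLADTDKQTKGVRPPYDHYIEKT
YHGFRCLLTSLVAIVATQSVPCFIGKRYLL
>C
CYTEFGCCLGMVALAERGRAPSSLHTMNLNSYPVFHIIGDKNLEDVNDKGKMGPYQAADVGIFDDLIILH
QQLCAALQLLDANQVGEVRWGANLDEAPPLTLSGDMRATKERDRDDSAALDAQRVIAEGIISAGVNAPSN
HAQPSLTLEQRAQTAGTDQTQLVQIPWFYMNDFCCSSFTQLLAEKFMLSEEVYGSLQYTWQEAEQYLMQM
ALKGVNRKAVRESTSPKTVDMDAKYEPILLDEVEVIFTIQASKIRLLGQVSGRVIWLSQSGSQALSIQDI
MLCRYKAKASDGLVRKNKGA
>CDPS
GLMWITPSPRYNLYLALVGDVVNNLSLRPCYAIKHGGQHSWAQHGLGTGLIEIQDLANEIIYIKPDGFYY
HIADRETGYLYCVLQRIPIDTCDKQWYHSGWADSRESAPAGAHLRGERPEADGPSNKPQENQSEVPFLKW
FNPQPFATGYEGVLPLAVASGRKGKDDTLPTFVGFKNVKEKVNGVPKDIITINARAVTGP
>CMeT
YEEKRRYPRVDPGGQVTGTQIRGPILKPQNNGGSAKQNESNPHTDCIGAQLSVKGQDREVSVEEKDFLKR
PQAKRTIKFNFGYISDMITEGWYTRILGSAQISAGCELSLNLRGKAFIVQVVDKHKHRYD
>CS
DGDMYEMNGRKSSLLQQAKEIQRFARATADLQDSHGKGCNDRSAPESQARLMCMMKDFSPISAMYLVQMD
QSIPERFANRNPLRTPMSFACTLPDTKRYTHVQSTVNGKVTTRPIKNRECAVIADDEVPYAIGILITELL
RSRVTYIMPAVFSEGTQFIDFEMDAALNGFPNGFKRPLLEAPEPLTGEALGEAGPDSTAPYHLEERLNKL
SKVNPFIPIFCNLMPEYLLEHATFFIAYFQSFGIIIEGGRPLSAAALGPSWQDADWRLRFEYGTQSAENA
YDFIRNADIALGFPVVDHIEIADFTVSFSGQTSKVKIVSD
>DH
ASTNSKCSKRDLGGHRRVTNIKWDYDLENSETVDVRYFSTTGVRTLGADEDPNGVEQYPSVPLSFVVAVK
ARKINGIMPQLQKVRQQCKCREPISSVVDSDYCSDAIVTMMQVGNLCFYEWANYADTLDWSDRATFVSCE
GELFIQEVGN
>DMAT
WEHKGSREELRRPAAKQFARSNGNKIVTSFYLKSMGKSDSFIIVTLRYGKESVRGNEAKDISAFPTAPYR
NLHTEMNHRSTIAADLIFPTGLGSFPEYSVNSSVLMADVKQYTLTRDPNGLACKDELNGGTGATQPRDSV
GPSNDLGNPFENAINYTEQWLPDSSIEYTVQESIDEAIFVGLRDQRVCALDARGQDGLHPGFGQLIHSLD
QDSCQICDVNVLEYKRSATLRVDRNVERCRDSMHTALSYISSGPHAANFPNYALGEYAKDAASRMEVGIC
NTYGNRIDVHAVTRALHFPV
>E
IDSQHNRKFQVAAQTTLADNNRDERLSGNGSCLSVRINSGLSTFIANVVIINKIYEQYKYTVGLTEKGEM
VQRLDGGGYNNCTKRVSLYPGDETHCSHVMGDYDIFQEPFSVTARNLVSISGHVYRTVKDYLQFCTTISG
HWSMMAMGLSAATRFGLEVQSFLKIKFDLMRSLFKLRCLCIVDYESIGCLRLLQDFNTDWIDYKGEIGGI
GPAHEPDDLGTYPGNENQQQMKLSDNNTKQHRGQAEITIPKIFEDSRPLP
>ER
PTRVADGSFTPLMKPDESGNGQDEDDEAIEILGVTQHRINLKRNGDAHMGKLGSYAAEVANEKAGIFVDP
IVKQGNVGLENEFTGSLGQCLANIVEMEGEMFTSDDEDGAALGSSGSKERLGQNGPFWEKDAVNSADLTP
CQKIMFAYFDSVLRMSSEDCSEETYSTHNYEVPGDSVMFTPRNAPAGYGKLMLENKKVGNLRGSTNMKPW
EGYQVARYLT
>FAS_alpha
GEFSITYFLEGGKDPALTLVVTRNYLTEASGPNAHLKSYSLLLVEDDIKEAQSFSYALPTAMVKSSVQVH
LKQVSGVPTSAQPTWVGRKNKTARDLALTSCVQYAAAFKFGEFDQASVNLRLLRHVAPKQFKDISITAWT
ASSGGTACWRPHAAAGFQICTNFGQWEWLFLEYGSSSLNEALQRIDVNQLYFPFTDPIDRLSAGDYIHLH
NMISFERDPVTWAVGKIVKEETDSRGNESHRHDRLGGLIEDNEKRKYKEISVCTMVAEITVALECPPEDP
QTCKFESITWRSSVKKAQPSLHQLLAEQHIESKVRDLYQE
>FAS_beta
TILVPRPILDAYNASRKPNLPVMAIDKAYRAIDISPESGKRFDYTPLTAYVAGTFELLGAGETWLFETAR
LRKELKQGARPSAQAFVDTGSCLEARIKTRVADCNGAGITPDIAKTNYVRLAWGDVLRLTPIQLGKHMSP
SMAALDKDCTLMLQPCAGGLAPHQQIPCVAAGAAQGGEMSSLGRFVIMNAEKTLLYQYKHYAIDSYAIKS
REWSGTDYGDIWNTVAPRPPPYELCTIASPAPITASQAQTFILYGAEFSARSYDERIEPENPLYDQPYNP
LGPAFVGVLFASNTIYKGSWLDYLSRKETFCFEGDSLRCV
>GGPPS
DQLVACVIHDILRHYQAGATNPISAEEDQPELSLVGFFLKELEHEVLAKFDRMFTADPESSPYNSIAAIK
FETIKSPQRPGWADKVTSCLEECSDRLAGKVHEMCVVIDTMMHSSASVISKKQVPNLGQNYCYVVYMNGI
SVNLGPGLIDALNVWAELLEGQKTQMPLMGSGGEVDETGGWSSKINGEGKINISPLEVLYREILQGCPET
GAQWIFKREETPDYTCEGPKSQLLLGKTPA
>GT
QHTCPAVMAELMQIPIVSITLPVCVGMHEPSSKDQVEKYQADNYVQGPQVDYQNLGMNPETLHETVRPTL
YLSVNAAVPPQEIGSDEHGGVDQFAWARACIFELMESNLKVAGLWVGLAIAVVNDAALKFVRLEAKSPSG
ISATDLTLNLKILGTLMANSYYARVLQQKTFSSEEKASAPKSELLYLRLLGTFDVSIQYAIMEAAEPGQD
LGQNDFSKSTNNIQHKPMGNVPTCCVGHSFQRQQKFTNLVGLMASLTLNAIAEPARLAGETLQAAAISLY
>KR
PWSQPFSFALPRDAWKNSEIIMIQPDRILQYFVRKCMSEALALATVDSGGPTEQFELQEKLSYVSGEALF
GPVTTITSLAQPVVDEGVEYVEGKLNMLRSDLLCGEIWGLYEGSVRFSLCLGLGSRIYNTQMSSKGHSFM
IINFFGWFIVLQINAGTSVHTGLKWGYLSRAVGAVSGQFGFQDQGFELGAVLANRSEANI
>KS
IATVANKALSLWMLPEGFGFTFDLGKCRPLQCVGSDGVAKECLNQLPWGDTAGVCDVNLGPAALTGKIYG
DVSQCQYEARVVNGVKAFARRTQAMMQPIIVNIVPCGALPKTRLGTFAVEKEGGSRWARMPVSIAAGRKP
NGGAPLKIALAHKPQEVSESSGENQDLSIEHRIYDLITWAGREGAFNNGDVDLRRETQVLCRNDLAVSRV
VVGTCPRGARVYHAQSIYLVQVWEFKGFVILFALLANLTSTIPKLEVIKAAELYVLYFFGAVMDVFHTEM
EYLQIHDYSDYLFRVVAAPR
>LSS
VPGANKRRGVLEDVENGLVKRLDHDVDPTMVLTFIYKMTTSYINDAQEKGGGLLQLPGEHSSVEQASCND
YAAHVYDAKLWLESFISDKQFFQEIDFMSAGFTLAVLKADPSILAGTKHGQTEVAPVYKTTLGGAEIETT
RWTATKSTRLISNIHEGIGAAGGPDVYGNENLVSRSNQEFGLPGAYTAGVYCHPYLGDAEPALWSEQLLC
GKENHGKVVNATTPFEMLKPMINEGTQMKHHGDAVEIVVREDMLAFLHSEQLNEEEPVLVESSGWEQHEI
LGRTSGDLLDPDEKHQKITHACNKNETSHVVWGPLSSYHISPLMEYIAERMNPAVGGILI
>PT
EGENNGTDPFISEGGYMNELLYDLRCPQAFSELSCNVVDLLEDAISSVNAILVITEVPTLKKTQPQPATP
GIYSAVVPGNTTDFLPIYIVIVACLYTPMEIKLPQGRRRMITVGECVKTGGNIGESKFYNAVIASVAKDA
LAKNALKAVLRLSNDAEPFVDQYDPGFAVSNNPRAARKCTSNPQQSRSAKVHKDMDGSYI
>PTase
PGPLGLDDGFPFLNVSRANIGQQPSKTTRQGEVTFRDKLDKNETKETVSIAFLLCRSGVANSGPPQGRVS
TANMLGTDGVADYIYLELRRGLKPANIVPQKSAVIWAGLDGTRNIWVVFVQACSRTATESLHHQLFNTFA
IIALLISENHEYCYKEPATIVSMESSIYYTDFGAGTTIIQTGKRKTVSILTRGAWLVEPPALDPKVHASS
LDVFPRGKNPKDSCVNAVLGGMFALRATKA
>R
QLRDICFQYNSRRVRGCAIQCEGEKHHKNEISLNIVVDQNLAVAQKASMWEEPAKSSAANTVGEGRDPKY
EISEVPPEPNPNVEMQESADIGNHPIPVRRFNVKIKCQSPRKSTGFAGCETKTEALGVAGQGVVGHANFG
VGFATILLQAAYDVNDSEDAWTKIMGQPNSKACNITAMTDFRVARATYGQGTGSKIGLIHFETPSQFGQS
AGVLGEESGFPTQQPGWPRPLMISGVASNNLVQSENKSNR
>SAT
PELTLQLLEEHNNIVADALIGSPLEDWAPSSIPLNAVACTPPTWKGRLEYGRTDDWAEVVFLIAGIILGQ
DACIGPAGPPAHVVMSQGSTNKLNYAINKKIKRQGPGPRQGTAGWGLIRKSSWYDFLHGVSARLFEQTGS
DRLRKTPQMESRTHRMKENQLCAVLKYHEPIYGGNKIDVI
>SHC
VEGTPEVRGVIDDEHNPLVKVLDEDVLPTFVLTYIECPTTSFINFISKKGGGLLQLMGKHSGVEEVEHRD
VKAHVYVPKGGLSSFISRKQFFQEIQFFDAGFTLVLMNADTTPLICTNHSHTYVAGMYKTTLGLQERETT
RWTAVKEDHAVSHIHYMINAASGPDVYGHEALSSRKSEDFGNPTAYAAGVYVRTWLGDSEPANQARKKLC
DKENWGKAVNWTTPVEMLKQMLEERTQMTNHCDPVTIRIKEWWLVDYDSEQLNNIDPVLVEGSNIEQHDI
LGRTAAAFLNWNEKMWKITSAMNHAEGEHEIWGPQSAFLISRLMWYIAEEMTMTVNGHLF
>T
KAHIAVPDFGANVAQHQIPALRPEDNARIFYLEKSSKMAGGVLDGETRDPRGAVEQSYVHKIQLGLCDCL
>TC
RAVDKNGVLIKDQATYRKLNNWLVVPGIKVVVEAKQPLERDTKALSTINVYTCGNDKEFRLPSLEAMARS
VLKEILWKSKKGDGDILDNKQNFAIKLEAYEPLSKSGMNKFDKAEWQEQLGGPLAVKFYGFRNCKHCCAP
DDIQEDLKGSYMLFFWAYEIPASCMEPGMRDVSVPEEEEIRDAMAMNNFSPHKFVIVTRDRKSWQIGPML
NAYFQDMDEAIGGRQLQDALLLGASLATTLNQPGSQRKSEMSNTKRIPRN
>TE
YDGGEEEYLKPVGLAATEDRSGFSYHNRVARRLSSVSAYTVPDTEQGVHAGGDLRPQQDPEDRTSGFSNR
DVNTFVYKQYRQKQNKSTYSSDNGNKNIEGSFWNCGSPQIMCHNLKIFAFNQPSPEICVNYPEELNYFER
DSCKEILNAVAKRFHAMELLNAMCLEVESNIISKSDPAAT
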