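>atp1 ATP_synthase
MNPSKGLHWAIDRKLYQTQLGQPTRGTPEGSDMLIQRPVRTVETDKPGTHGPLDREFCRM
IAKSHERLKAPEKGYKPKELLMENIYKSQQGTMHSGPLNKVLFCNSLMRGQLGDKPETNL
KPKQNSKPIDASQMDAKRQHITLRADGIHYDVGTQWTQFYDLGACGNLWILVEDANYPKG
DDPTDSKIKAKNIQAAHLIPSISILADQAMEDEATEFNGVAGFIQLSRSELQIKDNEIRD
LYMPGSAVKRVSRQDMSEEGHPSCAVDHDQSDISGSSSLWLSNAQEECMTDKVRIKKGSD
EHRATTDSSEEEIIPTEIRDPSKYIVFMTGFGKKGPNLFMQQQEDMRRSPEAKKSLLVMV
QVVHYLIILCMLDETKSPKKSSSITGKRQEIITYSAQTIGGSMEGSIGVDRFLCDGEDCE
RSDVPVGKQETHKTAGIIFALIDTLVVLNR
>atp6 ATP_synthase
MVVMIPTGFLEVAAWSMLESDTTGLVSLRHVFMQSNTIDMSTLDGDTDAVVEDMFDVNLE
LKPLRTEIETDSGTVVLSGLNGVDEPFVKAAAAIDGDTGGSPTEYYGLAYCSDRKEMPHY
VAELFGLPNKAPLGTELGDYGNFFARTPTELAESEYGPRGAPDSMKVFHQKLMRFWLLAL
PHRAHDNSQNHKVWLVMQFRKRRSGWNMAFKEAPSTTPQDWTRNNTGYLPKMDKVDKIEK
WEPCEGIMSGGQSQPIGGKKASGSQSGSTPTIIAYQLGTSSTLVYSSPDS
>atp8 ATP_synthase
MFTTNSGGALQVSMVYGTERVFYHLKITTLIYSSETKGNGQKTLGFMHSVREEWIEELNN
AEGPESINPLDLVDDRTRIQLCDLMSQDDGDRSTTILPMFNTHVTDREVGTVELGLVDCA
WHAHKSKELNVSEGADVNTEHEDKTARKKRPMGYY
>atp9 ATP_synthase
MMVYYDWTQLGVATDLGSNKQVKEFPLWKYSSYDHTMTIKLLSSISVVPVGEDTIPDGTT
TKVKSGNEDKPKQN
>cox1 cytochrome-related
MKHMNPYSGEGLPKGVSKVQSGTSDKDQSAANFLKQQRIDGRMQAERLLKQKGMFTMGVR
ILEGLNDKRSREPENKFPMTAGVAPSDRSQAPQTDTVRKPTGHLLRSHWKPWKNGVTQGF
RVDTHIADEIFEKDVSVRDSQEMSLEPNCLLVNTTDHAQRYSRTFPVCHLTFYDSPGLII
AASKHKFRGDSKNITDKTKVSQGISWYAGEQSVAGLLRRTLPADDGADEGRKVSFYLVTP
VGFEVFTSPNDSNPAVRDTQHAEESPTRFYDPWTLINRMPAQGVVYLFIFLTVSSTNMDE
GSTPLKKAYLDLKQSNVRRSVLTTSRSEEETLFKIKIEQKKSRQDGKNGPSETKDGDSDY
IIVENFEDTHQSPWTVGHKPANQRPTATPIAEGNRSYFALSDSMPEGFFPVVDRLDSRGI
IVPALKLQGGLLSASCGASGDQTMRPSACAPATRRNNEYKDPRRNLVDPTVFLEQNSSIS
PLTQSAKKSDTDEQSLDFNSTNGPFSSYDDRTRMTVVTRR
>cox2 cytochrome-related
MLFVTKLSDMFGTFSRDPGTYNPEPDFSLPQEGYNKRATLSLASQSAVSPIYTDCETVDL
SRDDITPHTESSGDAGTLRKRLNENAISKTDRCSDNDERQTNPNPKKAQDYVTSQQHYNV
TLILAFNPIKIPWSGGELDSELNRPDSNYSVEKKLASNTYFNIESNEDESAVQPEDTPKR
GKVSLNNRRAAWLWSSQKVKKIHLDRKKTANDNGKNSSVTDATETLETAELEADYIPSAS
QEQLYVNITYVRHPHTPVST
>cox3 cytochrome-related
MLDKVNPGLFKDSSEMIFEESASVRKTPGLMARTPNLGSVNEEIPVRNMSLNGDKKAEIW
SDRKLRAQQGIRCSVNLFETEVPTPTLNICMEFCTSGDNGSKTPYKYSIPSGADELDALG
LNYGCPFGSNNDVVSLKINTPYPDSGSAILSSRFVEAISKDEVKRKDCWIANVTVPSEVP
KSSDQAKGLIERDIEDTAGDGFKKSKRPSYTGEVSRKGLVHDVDGLRREGEGPQKLRQMA
PEVTIDKTPMRTPPAMEGTLGLGPR
>cob cytochrome-related
MPTESKSDQSREVQRAQPEPWDRNEIQPGWMSFEEDLECVSIYDAEDHSKEDCRSAKRLK
GPVNQSSFVSTTEMAKPTNTTQPPGEVFNEGKSVSSRMVRGPPLKLPKHDAEKISTNNKH
DNMRSLRVVHGISEFLETLSLIADEYDSDGMVSLIVKVAMSPQGRTPHSFNQDYKNKYKI
HKSSDKPAINLTDLHPKNSLHINQETSFWIEEEQGSRDKWGNPLSGKETGDDMQEDTRGP
TVEFTEPNGLDPSDFSGVLSAQNYSTLQYHSDNSTPGGFQDDRIILALSVCSYGNVPFDV
QEAEDSADSRFTKNLLGRALEKRTLHANKDAVKEEDPDDGSIRPGRSRRDLVFGLNKKLR
ETWSRQTQFKTSVHTRIMVTQEKTTLIDSQ
>ccmFc transport/maturation
MDWTQDRKPRYYGHSWPPKISPSEQMFPYPKSNPHFHSKGMGTDERSHLARSRKIKPFEY
FAGRQTLRSAGSRAAKPLPSHYKVWDAIKVEKVSSAKIDITGTPMWTPDKPPDVGDYTNR
GRQAAKKYRHGRSKPRQPYLRLGVKNFHDCMQGERLELGIEKYEGESNYSLKSEPYLLAI
GDNSLDSKTKSKLNQSETWGMYNGRTIDGSNDVAATNLEDEAHFIPRKNTMADSKQYYRA
PQRVGGDLEVGPGVAELKIKGRWQEKTPLKTENPGSLSMVDNILAQAASKPTVKILQRPR
MRRELGQDRMRQDPPHRTESMIRILVFMDKAYPGGTLIKEHKSPEQEDTGIGGQASGDFQ
TSRYDPWSLLVEVCAGLGVTSEVRQNNETRDLLYVTEDEDGYNEKNYKTGASQTLLYYLS
KIMNLIPGALEADDRQPQLT
>mttB transport/maturation
MYARMCPGTDNQHEDYIYSHVSLRLQSAQPQLGEKVKEKYDYMNGTSDVLEGSSMDEREK
HHKSSSGPKPRLQTHADDWHGLKNSFSNYGAGFLRRAVRPLGGNAVSDSAVKLGLQSLRG
IPDPYVTTRTTSQPGKQSYGLCAQSPEPAQAIIQCFSTPDSEQVTVARLLPTPYMLVSDV
TFVRQAQQPSIDAVATQAQINHLGSEKDPHWKKGVLISKSLGNKQTSDLRKGNKDPESIT
TRKLSGEITQ
>nad1 NADH_dehydrogenase
MTHQFRTEVPGDEYQPVNQSSIEADYYLELKIVLLTAVPSGDASDIMFCLDSTSTRQNGA
CVNRDMISDTVDREELAKPLERMKEEYMMSGKVHYFRSTLVISVQPGWDAARDKVLFVIL
LPFLHMDSDFRMNQNEIYNRYLKSQDSPYNEGTKPETGHYRSELSGNDMSSTHSFPLGTR
MDWTINDEMLFPRSDYWISKLDPSDNHPDKWQWGPFAKPMMVRTNSGSWGRLIVNPQNLH
LDKTVLDMASSRAVTIYIPGRKLFGSGITTSAANVQGSLPSGLARPNRENVVGDGFPSGE
SPTKTLMLTPLRTNEKADRQIIKRS
>nad2 NADH_dehydrogenase
MGAVDHSDQGLSHVSKDWTPTHGHANPKTDQSQTNPDFLEDTGKIRHGKDVKMNNKPEEV
TKAVNRFPQYLHNELMGGGTPASECNVICEEEMKPPEKSFSTDTVETIQKRNLQEKLAYV
TTQDIRATTNRDTQEVGYPTGRRGAPGTTYGLDTEKIYQFADRVIRIHILLKCSEVKPVL
SGCPQANLAPKVPAMEKFNVPDLETSIQMHAILKRTKPKFTALNADLREKYETEKSKNLP
KFDRTSPENWSLDSTLSLEDAKHKSDDDRQFSVDHFVLNHESNSSEDFLDGIQGGQTSIA
TILEALGRAAYKSTGFMTWTQWGKDMDLIQTVESVSLTKQEQMRACGKGGPTTRILEDFG
VLMKSPIDIGNPKNPLTVAKLDDLSSAKSLEPRPFSAPEKDEIGVWITDCTLAGLLKDAR
LNDYRFMDTTSKVQQESIKIGISSDFGFSVKKTQKQSTEGQIRRNSVVYIRRRASNDNDV
>nad3 NADH_dehydrogenase
MSLYQQFEVTSGNYPKVVGGFAPPGPYRDEGSDKSEDTPKLSADHDLVSNNTLFSTIPVP
AQLSKSEYDTVLHSKRRSLLYNADVVTDTRYTDVKDTDGDQQPDIPTIFIKLLMWLYD
>nad4 NADH_dehydrogenase
MQTVSKGKKIHEPFSCCLKTVGDGRVASVPIRGDVAQEPPPVLVTDADDQIIVQVTGSGL
GCHYVLDNTPNLTARRPTYVPNKTSTDRLSPKEAFSASSLRTSVNVPRLTDVITTLGLKE
TKNQRLDKPIFRADKGQSVLTNDSQELTDIITSEEDRTTGMMWKSHLKTSLSKHALKAVS
ANLGRDQSYFTKKKPNSEVEPQITMKSWSVLIENLKHERPTSTLKSGYEDRIAAQRGTSL
PTQVIKRVKMPVLVYIDGSYLIGGRITSSLLPRGQPAISQFIQAVSDTEGPNGMSKKRGR
KKTGRTYNDQKVNTFKRYQAILDMVNQSEIQYSSINMSHAANSLKGVTPRPTTRKNDRLV
YMILGLKEKYKEDKSDLLTTTKSTPDPNSFTQDTPTPDQRTASGGSRFTFLEPFFREGLE
GPTMYFNIEPKDQNYLVRPNQSSEGYAIDSVSEEYNRPFEANPLIVTQDDNQSNHDPLAL
GSSEYFVYKD
>nad4L NADH_dehydrogenase
MGAGVTYRSFLKGGEKPNSTGTDKRVAPPVQETLWAWIYQAASVDEGIDKMIVIARDSAT
KSDPYKARVRIELSSYIILFAQRPENQPLPSGAIFVKKDYT
>nad5 NADH_dehydrogenase
MGILPSEQVTSSKHNYNLQLMMNQRYSSALELCKQLEISSDDRPRDTHSGLLHMDGKLQV
PTGYDCSSTVLAATVKTKASIKESKAPFKTATRCHFLSFDSTRELGLMTTTYNAELVEAN
IAYSKEAGRAIIPGANTQGAATDPVKRPVVRIRTLRHNRGGYGSQRFRTKPLFQGNKGLI
TPPYDPVQLGYPFLADFRPWNKGPAKRNIVKPDEERKDTLIKILGSRHDNSKEAPRLQQS
LWRLLIENHESTIDCLAYIKGPFKHSPGTSFGLFDPLHSHAEKQMPDQSHIGGQVTSNDT
GAYIKVDEIQQLTIRQIGITQSSYEWVAKESNTIVEPLPVARVARQESGWTIRGGGASNL
HIGCLAIQQVGEFKHVPELPGMQAPRFQYDDAQLMQWVLPLDSQPMCADGISGIEGDPQR
HPVLFKGVDELTLVNSNSSNNILISVDARLHTDLCVATAAPNDCEGTKQPSFSDGNPSLT
QRASDIVDDIDELAKGRHQFQKVKVGQIKAEQKHDPVDAASEDVTEKRTGSYHKEMKNMM
SNQKIALFYGIAKAVHDSRE
>nad6 NADH_dehydrogenase
MQATNISLYFSGSDPDTALVGNPETYEPFQARSELLYGDLVPGEGETERMVVKPPTSNEG
KSPSVDLDRMGPSLISKGAALTLSVILLMILNIEFSEGEKNHLKMTSQNEATVPAKNGLM
QFSVKHNGEERHQSLHTKYLFILASPVVQSNAGSFMLLDHLSKNAVRTSVKTYHPGDAQG
QNYEAPRSKMQSYPAVGLLKEQKEA
>nad7 NADH_dehydrogenase
MQPRMHLVTIEGPGVQIGVVGEDTEELVLMQTAFGKWSKEKPQIVKFLIKRPEYRRVLDT
IPLQKAMHYQYWRIQASYMKKGASIECQQVVKLVFAELKFPQQLNSGRTADDGPSDEARK
ITSHEIGQGNGVWVKGKSISQRSVRRTLVRGGHVSLPQFVCAMNRGFFSACTWASLDSTH
GLSALYSQEMDRKLSPFFGRCLKNPNGADIQIRSTYTAIFSTSAGGRYERLLGMKTKYQP
SDMSIRSAGGNGGDPRRLPKKCAFKYVRRLSTAQIRQITARPKRKKELMNWDIDKLHTKS
RLSELGDWLSTPDPGVTHESQFMNDTKSPTLDFSVIRKQVAMSLLEFSYDSKDIYVATSL
QMVKSAQFPEEAKPQTPTNKGGSKDSGTSE
>rpl2 ribosomal_protein
MMKSNESESTYIGATPMGEFNLAYDIERKSGDVSSFGDSDDDKESGTLVGHVQRSPRARV
HDDPESPKGLLFPSPFSSSQAMQGPVVEKPNLLRCRLQQAPQESPLEGTDIHIQRAIQRV
IPIYYVADRSSLTDESLSRAYFLEELVPKILGPEYRGQLESQLESLDNASIMYSQEENKP
TKKTESGYRTQLGMGVKLIVVNGARGNSLKQRYSPLRGEYKEQDGVGFPMMKPEAQSDDG
VKNNLTCDTRPIKVYGGKCYVAQFEAIENGRGGQLQSPDITQYTPIDAFMNMRGYCLPVK
KTVREMEKGKKPVAGLPTLLDGTIHEAPIDDQASYIIMADWTVLELSTITKVKGVKSGLV
QRAQAYHGSY
>rpl10 ribosomal_protein
MDKDEVTPGPNKLNMTLMSPELKQDIYDMIGAVANEVKAIPYKGYWEAPTIGSPGYENKG
IRSGYHHQPPHEKRKKTERESPSEETTSDQHANLTSTKFNIKGGYYKQREAYSTPPIPAL
KGLFILSDLEQGVTRDIEQYKSYGQEIKPQHVSLPLGFRS
>rpl16 ribosomal_protein
MMQKPRGDHSNPEDWTDESVAFPTHSKLNHADPHESQSGESKKHHDQLKDSLGAGLHYDD
NALSGDRLAIPQTTEPGLGEEGFAGGSMLRNPAGTHSIIGASRLGKSSIN
>rps1 ribosomal_protein
MNQGCHNGPRRKESAQGPSAPKYAELNVEAADGPAEPRGDMSETSVSIWIDLSGYYFLEL
VLVTNYRSLVASHTVVDSEGKEGRHDCLTTSCGLPYNTRDDGNIARIKKAYKPWARFDQK
AENAEESITASDRNWDSQRQGQGLVDHASGKQRSAVEFPSLLHSTDVEPVILRDELHNQR
SDKYDKSDARSNEKSSSKPD
>rps19 ribosomal_protein
MNSDPEIAVESLSLDKEGGLDSPMWSCGVGMLHRKVYPSNCLVKRNGETGKGRETPISMI
IKPKSIPSDNSLEQPTPIALGVNPEKLIREFAAFL
>sdh3 succinate_dehydrogenase
MMHQFRTLAYSSPLSMDTAAPANTVGAQTPSSALTYTQSNSSDRIRSVNWTPSAETDKLP
GRHGQMSYAAGKLGTANADMLSYIYGEDQRSTSPCYVILF
>sdh4 succinate_dehydrogenase
MSAEYSEGIQISCSFGEMVRQTKQKPIKGFYMLKSTGLGFEADYYYQLFKVLLNWTFNHG
DLTEEPSNSLGNYVQYIAGNYRKFYKITDGEVAERSVPPTSWGCGERGSEFLEDDNPPRD
GKLDLCENKS
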