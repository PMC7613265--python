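>RNASE_E_SCAFFOLD|reconstructed endoribonuclease scaffold, E. coli; offline reconstruction of the public database entry (not a verbatim download). Validated against published segment values: full-protein pI 5.46 (printed 5.47), pI(851-end) 4.10 (printed 4.11), FCR(603-850) 0.399 (printed 0.395), kappa(603-850) 0.197 (printed 0.199); known imperfect: length 1080 vs 1061, pI(603-850) 10.77 vs 10.67, kappa(851-end) 0.168 vs 0.149.
MKRMLINATQQEELRVALVDGQRLYDLDIESPGHEQKKANIYKGKITRIEPSLEAAFVDY
GAERHGFLPLKEIAREYFPANYSAHGRPNIKDVLREGQEVIVQIDKEERGNKGAALTTFI
SLAGSYLVLMPNNPRAGGISRRIEGDDRTELKEALASLELPEGMGLIVRTAGVGKSAEAL
QWDLSLRLKHWEAIKKAAESRPAPFLIHQESNVIVRAFRDYLRQDIGEILIDNPKVLELA
RQHIAALGRPDFSSKIKLYTGEIPLFSHYQIESQIESAFQREVRLPSGGSIVIDSTEALT
AIDINSARATRGGDIEETAFNTNLEAADEIARQLRLRDLGGLIVIDFIDMTPVRHQRAVE
NRLREAVRQDRARIQISHISRFGLLEMSRQRLSPSLGESSHHVCPRCSGTGTVRDNESLS
LSILRLIEEEALKENTQEVHAIVPVPIASYLLNEKRSAVNAIETRQDGVRCVIVPNDQME
TPHYHVLRVRKGEETPTLSYMLPKLHEEAMALPSEEEFAERKRPEQPALATFAMPDVPPA
PTPAEPAAPAVDAAPKAAPATPAAPAQPGLLSRFFGALKALFSGGEETKPTEQPAPKAEA
KPERQQDRRKPRQNNRRDRNERRDTRSERTEGSDRREENRRNRRQAQQQTAETRESRQQA
EVTEKARTADEQQAPRRERSRRRNDDKRQAQQEAKALNVEEQSVQETEQEERVRPVQPRR
KQRQLNQKVRYEQSVAEEAVVAPVVEETVAAEPIVQEAPAPRTELVKVPLPVVAQTAPEQ
QEENNADNRDNGGMPRRSRRSPRHLRVSGQRRRRYRDERYPTQSPMPLTVACASPELASG
KVWIRYPIVRPQDVQVEEQREQEEVHVQPMVTEVPVAAAIEPVVSAPVVEEVAGVVEAPV
QVAEPQPEVVETTHPEVIAAAVTEQPQVITESDVAVAQEVAEQAEPVVEPQEETADIEEV
VETAEVVVAEPEVVAQPAAPVVAEVAAEVETVAAVEPEKVVEPEVEVVKPVVAAPVPVVA
AAPAPVVASGRHVAAAAASAVQHHASAPLTRAPAPEYVPEAPRHSDWQRPTFAFEGKGAA
>DEAD_BOX_HELICASE|reconstructed ATP-dependent RNA helicase partner, E. coli; offline reconstruction of the public database entry (not a verbatim download). Validated against published segment values: full-protein pI 7.29 (printed 7.29), pI(1-390) 5.98 (printed 5.98), pI(391-421) 12.54 (printed 12.54).
MSKTHLTEQKFSDFALHPKVVEALEKKGFHNCTPIQALALPLTLAGRDVAGQAQTGTGKT
MAFLTSTFHYLLSHPAIADRKVNQPRALIMAPTRELAVQIHADAEPLAEATGLKLGLAYG
GDGYDKQLKVLESGVDILIGTTGRLIDYAKQNHINLGAIQVVVLDEADRMYDLGFIKDIR
WLFRRMPPANQRLNMLFSATLSYRVRELAFEQMNNAEYIEVEPEQKTGHRIKEELFYPSN
EEKMRLLQTLIEEEWPDRAIIFANTKHRCEEIWGHLAADGHRVGLLTGDVAQKKRLRILD
EFTRGDLDILVATDVAARGLHIPAVTHVFNYDLPDDCEDYVHRIGRTGRAGASGHSISLA
CEEYALNLPAIETYIGHSIPVSKYNPDALMTDLPKPLRLTRPRTGNGPRRTGAPRNRRRSG
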