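>P01857|heavy|constant|isotype=IgG1
LGDKPETNLKPKPNTKPIDASQLDAKRQHITLRADGIIYAVGTQYTQFYDLGAAGMLYILVEDANYPKGDDPTDSKIKAKMIQAAHLIPSITILADQALECEAVEFMGWAGFIQLSRSELQIKDNEIRDLMPTKGLHYAIDRKLYQVQLGQNVRGTPEGSDLLIQRPWRTVETCKPGTHGNLCREFARLIYMPGSAVKRWTRQDLSEEGHPSAAVDHDQSCISGSTTLYLSNAQEDALVDKVRIKKFTDEHRATTDSSEEEIIPVEIRDPSIYIYFMTFFGKKGPNLFLQPPECLRRTPEAKKSLLWLYQWWHYLIILAM
>P01859|heavy|constant|isotype=IgG2
LDETKTPKKSTSIVGKRQEIIVYSAPVIFGTLEGSIGVDRFLADGECAERSDVNVGKQEVHKTAGIIFALIDTLWVLMRVVLINVGFLEYAAYSLLESDVVGLYSLRIVFMPTNTICMSTLDGDVDAVVEMPTKGLHYAIDRKLYQVQLGQNVRGTPEGSDLLIQRPWRTVETCKPGTHGNLCREFARLICMFDVNLELKPLRVEIETDSGVVVLSFLNGVDEPFVKAAAAIDGDTGGSPVEYYGLAYASDQIELPIYWAELFGLPNKANLHVELGCYGNFFARVPVDLAETEYGPRGAPCSLKWFIQKLMRFYLLALNH
>P01860|heavy|constant|isotype=IgG3
RAHDMSQNHKVYLWMQFRKRRTGYNLAFKEAPSVVPQDYTRNNTGYKPKLCKWDKIEIYENAEGILSGGQSPPIFGKKATFSQSGTTPVIIAYQLGVSSTLVYSSPDSFVTNTGFALQWSLWYGVERYFYMPTKGLHYAIDRKLYQVQLGQNVRGTPEGSDLLIQRPWRTVETCKPGTHGNLCREFARLIHLKITVLIYSSDTKGNGPKTLGFLHSWSEEYIEELNNADGPESINNLALVDCSTRIQLACLLSQDDGDRSVTILPLFMTHWTDREWGTWELGLVAAAYHAHKSKELNVSEGACWNTEHECKVARKKRPLG
>P01861|heavy|constant|isotype=IgG4
YYLVYYDYTPLGWAVDLGSNKQVKEFPLYIYTSYCHTMTIKLLTSISYVPVGECVIPCGTVTIVKSGNDDKPKQNKHLMPYSGEGLPKGVSKWQSGTSDKDQSAANFKKQQRIDGRLQAERLLKQKGLFVMPTKGLHYAIDRKLYQVQLGQNVRGTPEGSDLLIQRPWRTVETCKPGTHGNLCREFARLILGVRILEGLNDKRSREPENKFPLTAGVAPSCSSQAPQVDTYRKNVGHLLRTHYKPYKMGVVQFFRVDTHIADEIFEKAWSVRDSQELSLEPNAKLVMVTAHAQRYSRVFPWAHLTFYDTPGLIIAASKHK
>P01876|heavy|constant|isotype=IgA1
FRGDSKNITDKTKYTQGISYYAGDPSVAGKLRRVLPADDGACEGRKVSFYLVVPWGFEVFVSPNCSNPAWRDVQIAEESPTRFYDPYTLIMRLPAQGVWYLFIFKTVSSVMLDDGSTPLKKAYLCLKQSNAKSHDSLKAPEKGYKNKELLLENIYKSQQGVLHSGPLNKWLFAMSLMRFPWRRTYLTTSRSEEEVLFKIKIDQKKTRQDGKNGPSDTKDFDSDYIIYENFECTHQTPYTVFHKPANQRNTATPIADGNRSYFALSDSLPEGFFPVVDRLASRGIIWPALKLQGGLLSASAGATGDQTMRP
>P0DOX2|heavy|constant|isotype=IgA2
SAAANATRRNMEYKDPRRNLWDPVVFLDQMSSISPLTQSAKKSDVDEQSLDFNTTNGPFSSYDCRTRLVVVVRRLFWTILSDLFGTFSRCPGVYNPEPCFSLNPEFYNKRAVLSLATQSAWSPIYTCAEVAKSHDSLKAPEKGYKNKELLLENIYKSQQGVLHSGPLNKWLFAMSLMRFPWDLSRCDITPIVESTGDAGTLRKSLNENAISKTCRASCMDERQVNPMPKKAQDYWTTQQHYNWVLILAFMNIKIPYSGGELDSELMRPDSNYSVEKKLATNVYFNIESMEDESAWQPEDTNKRFKVSKNN
>P01871|heavy|constant|isotype=IgM
RRAAYLYSSQKVKKIHLDRKKTANDNGKNSSVTCATETLETAELEACYINSASQEQKYWMITYYQHPITNWSVLCKWNNGLFKDTTELIFEESASVSKTPGLLARVPNLFSVNEEIPVRMLSLNGDKKAEIYSDRKLRAQPGIRATYNLFEVEWPVPVLNIAMEFATSGDNGTKVPYKYSIPSGADELDALGLNYFAPFGSNMDVWSLKINTPYPDSGTAILTSRFWEAISKCEWKRKDAYIAMVTVPTEWPKSSDQAKGLIERCIECTAGDGFKKSIRNSYVGEVSSKGLVHDWDGLSREGEGNQKLRQMAPEVVICKTPLRVPPALEGTLGLGPSPTE
>P0DOX5|heavy|constant|isotype=IgG1
LGDKPETNLKPKPNTKPIDASQLDAKRQHITLRADGIIYAVGTQYTQFYDLGAAGMLYILVEDANYPKGDDPTDSKIKAKMIQAAHLIPSITILADQALECEAVEFMGWAGFIQLSRSELQIKDNEIRDLMPTKGLHYAIDRKLYQVQLGQNVRGTPEGSDLLIQRPWRTVETCKPGTHGNLCREFARLIYMPGSAVKRWTRQDLSEEGHPSAAVDHDQSCISGSTTLYLSNAQEDALVDKVRFKKFTDEHRATTDSSEEEIIPVEIRDPSIYIYFMTFFGKKGPILFLQPPECLRRTPEAKKSLLWLYQWWHYLIILAM
>P0DOX6|heavy|constant|isotype=IgM
RRIAYLYSSQKVKKIHLDRKKTANDNGKNSSVTCATETLETAELEACYINSASQEQKYWMITYYQHPITNWSVLCKWNNGLFKDTTELIFEESASVSKTPGLLARVPNLFSVNEEIPVRMLSLNGDKKAEIYSDRKLRAQPGIRATYNLFEVEWPVPVLNIAMEFATSGDNGTKVPYKYSIPSGADELDALGLNYFAPFGSNMDVWSLKINTPYPDSGTAILTSRFWEAISKCEWKRKDAYIAMVTVPTEWPKSSDPAKGLIERCIECTAGDGFKKSIRNSYVGEVSSKGLVHDWDGLSREGEGNQKLRQMAPEVVICKTPLRVPPALEGTLGLGPSPTE
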