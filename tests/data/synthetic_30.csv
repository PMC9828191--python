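id,fitness,trait_1,trait_2,trait_3,vol_01,vol_02,vol_03,vol_04,vol_05,vol_06,vol_07,vol_08
ind_001,14.220200691250987,8.528019695982941,9.460666291270808,9.608165276835473,0.388999400671198,0.45781840481852815,8.436571244810157,0.22484253104501584,0.6294782970478642,0.0185080080076093,0.4424937600286424,6.4367154057275755
ind_002,10.342761556975034,12.379329635681254,12.069457327187653,8.763198352762783,0.862573641375926,2.3910251744285778,0.5387939582106194,1.6787640713756766,0.2781321173206193,14.617976377785018,0.7330811987438184,1.0594244737708536
ind_003,1.2555214468422315,10.915216521417115,11.696104567184172,14.545207433277577,1.0389365069860443,0.647134172118732,0.5571213612489168,2.31023909359886,0.36907187105728273,3.625387268373409,1.05470740482839,2.1572556730738235
ind_004,10.605343970410402,6.641701806491617,7.9692155725931375,11.231611719992646,0.7463620759133287,1.1192253726789665,1.3370204803143022,0.7556543594079396,0.7346988883029452,1.616191189198309,0.5716386865555312,0.9994784326542893
ind_005,10.130572636526392,7.289859402786615,6.898532877715471,9.618761797542316,0.8192951171421013,2.0870364976434503,0.5920374908154982,1.0481166435854412,0.34730532700750477,0.7742986314887098,1.5534255994168895,0.9669984565963088
ind_006,19.918727438353564,12.036817321757567,9.33528413626701,11.31932111707711,0.7367963847188536,0.6704600928576858,2.0773838871479446,1.0046056867441033,4.842913317914731,0.11336550272041789,0.7563254117912958,1.0313548735770577
ind_007,9.627886697607385,10.233910538859893,12.967761642987146,10.736028622552757,0.906658375749037,1.5677683709130674,0.6808692513777166,1.3520824061579237,0.8776821528453622,3.0354828129161198,0.9802398170166672,0.12585331027461205
ind_008,14.455244337041147,11.980494623936133,8.871109328181577,9.853318234758705,1.4134946745547239,1.234249117016311,1.977654281225055,0.9245101364979548,0.23548309256181119,2.503126526183056,1.1418161481388664,3.3109345502929552
ind_009,16.09695918082172,9.806591092476362,12.115256779246412,11.519486524243625,0.8068468608601214,1.6070270829326831,0.33998096013888546,1.1342410232437552,0.30381781586174245,13.646515435217973,1.2588439620245884,0.651344668203073
ind_010,6.350382466328698,8.49649373741286,10.850059688977733,11.27979060815652,0.9669464052287263,0.3820239176191727,1.957292367879833,1.0742861980054115,1.6088641350071196,0.32648854478203004,2.633713261912263,2.35336095906973
ind_011,11.928497979169656,9.776708555361106,9.44142420053496,9.459796255983033,0.39091787327100336,1.3965873020513673,0.6403995259082157,1.9141682963731397,0.7411630993136576,6.7899760506430695,0.9272824759658498,0.1626067874545599
ind_012,13.096156601284047,6.610015188022233,9.343103265293529,9.501570485943262,1.2252651998409947,0.5193430668106042,1.1253363892989603,0.6520661321977467,1.6189306303160031,0.12109909754247962,0.8760374272224184,0.6894848465416505
ind_013,6.79391711968351,8.268942952482021,10.897180051146263,7.258815845670206,0.6301825092100086,0.4749173420190615,1.5698611572333323,1.4298911904629095,2.0941420268140103,0.05692125180887399,0.9352408003877744,0.378289343051535
ind_014,12.777705223457524,8.896374357214086,8.762252108820414,13.149260355643294,0.437100419480325,1.562900223932703,0.4683232738212744,0.9451486584064102,2.450562128232531,1.6289263076314882,1.1422044453223823,0.07572555814312805
ind_015,9.764578260840064,6.801631873484238,10.11391967473422,11.037144825724786,1.5187905357259666,0.8613939112624972,0.6276105859979054,0.9740045568868866,0.46510354664055953,0.2285354115723159,0.7788758879257218,3.715622510064746
ind_016,6.930093141938185,10.755451128079734,12.481381191753268,8.88549718811394,0.7789226527304098,0.30217076497219225,3.6132575163278386,1.082313068646275,0.33119920073749703,1.1036369106614108,0.9499980747461741,1.1352822957634692
ind_017,12.28898457693001,5.439482795375622,10.09484012788573,6.749545347547096,1.0061725486254356,1.3475734057282116,0.9317531001379008,0.7057088711972653,0.3847676018301945,5.852142129574282,0.4610502581004717,4.36573232694774
ind_018,8.172456250735276,9.34720024690813,7.555065255318529,11.238686593477711,1.1372914009029025,0.38153499745275726,1.2817419842911357,1.0000894451806657,0.6038965049908419,0.03189007690047571,1.0083849621822962,0.8462970379488507
ind_019,13.267148723217455,11.730300469734843,9.145296231702613,11.879286705680208,0.8881288240741098,0.7553766643027945,1.9056377719716444,0.6614533114204326,1.0305088922018584,0.4850764224022667,0.3314554343581962,3.2152749004644523
ind_020,6.570769360088393,10.242554518639432,9.806829416170615,10.117983546175592,0.9158961722145692,0.5360511944917655,1.851546381201664,0.5753520828020413,0.4346658581309382,0.32638170234136593,1.20862541895046,2.1780216994662362
ind_021,11.708999371962921,9.594501280300088,11.051705644544132,10.725248294758154,0.8276038455040465,1.2499070571625805,0.6096908257452412,1.2145263633810401,2.6161628679578697,0.31028449120449875,0.6155705041866613,0.31395936617149894
ind_022,0.0,9.301065707132356,11.710133317308719,9.098221343074037,0.38520570408173704,0.8356083106012406,1.962300372157862,2.3302273059112997,1.1105614309427323,0.3534562406955749,0.8903736807757799,0.8541229394572195
ind_023,8.903465386470316,10.573867286134904,10.977581301293085,13.103257291425564,1.874218298875452,0.49371397669554323,1.2460593396738622,1.1224998308849221,0.4456071410186319,0.3624315261190246,1.05208314614441,1.692379668059699
ind_024,13.563708050006564,8.989117273302064,13.02232453566511,10.791208310750706,2.453063887297398,1.314025510243466,0.8898495399496702,1.3235725360104762,1.4831373950202527,1.984151733573072,0.7488656617336698,0.4074795230012955
ind_025,12.169076011754719,9.612046178694854,8.600617615598386,10.675922303723372,1.1458260027781932,1.2954369591088157,0.391990505477832,0.7588621524609628,0.20782597717523277,6.061344319483491,0.6855273268416309,2.481422359708633
ind_026,12.776780948089057,10.097870488884762,7.923808863034441,7.449675099995662,0.6200979201264433,0.23390327340192754,2.5957140098802287,0.34578112421596113,0.43013780948646174,0.023888110385441783,0.5711983545201104,13.12391583442196
ind_027,13.069541728697743,8.888961584398933,8.376951220347834,11.393074452321878,1.5534998269496565,0.7688253988154161,1.6213397136782204,0.5571567258210317,1.1535813414698926,0.6383144175941781,1.288476779951071,2.7771185091650765
ind_028,6.8482069572206505,12.751076595940358,12.482429126732455,11.872073428308951,0.38759036984146766,1.4824031773291961,0.4567853365054772,1.137156080625607,0.523389965283413,1.2168296666195284,1.0051898966013288,1.5711486451199466
ind_029,4.306143240535342,9.143523584310785,9.847004416725015,11.409399016962222,0.9477407132462062,0.478427602510082,1.0768289114718423,1.6601161685799768,0.41204485754218184,0.42080297269958866,1.277990840836593,4.06103716446422
ind_030,18.317360684045088,14.261944467446625,13.020284017993502,11.159962230052843,2.2825869988969267,0.6223593732867204,2.0806485395194674,0.32398952022009225,0.3174063067240405,0.5521895241495671,0.7304243133263231,34.58469901627942
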