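identifier,c_obs,c_pred,peep,driving_pressure,tidal_volume,frequency,c1,c2,hb,paco2,fio2,sao2,pao2,svo2,pvo2,sao2_o2,pao2_o2,svo2_o2,pvo2_o2
synth-0007-000,33.75286399814001,95.88855203878302,7.477279089896511,15.756856902451936,0.5318390480666139,18.202327988757155,2.0,0.49517738068086936,13.106142091913831,42.019024292655814,0.7188277715008186,0.9410514991894501,90.0,0.645454864022897,37.784256121007736,0.9760421234405031,90.0,0.645454864022897,37.784256121007736
synth-0007-001,28.352289176479395,80.18193035831814,15.95050311777832,13.534973520744924,0.3837474832561515,25.09726686899254,2.0,0.3268448869618777,10.076543491177995,44.18809406409546,0.46408481354313785,0.8394158065699711,90.0,0.6065913011942075,35.35680278773596,1.0,177.61931607373177,0.6065913011942075,35.35680278773596
synth-0007-002,28.986180759758675,96.68671092771409,10.655294112594653,14.292262544910106,0.41427810559269285,20.95622809550906,2.0,0.23147125178059508,9.962010719926553,38.00910085980493,0.6768128483527357,1.0,181.51429470274613,0.655430446590331,35.03734242052076,1.0,428.95206912475084,0.655430446590331,35.03734242052076
synth-0007-003,19.633832431843196,70.70397218255141,10.607698908552655,16.803321539808287,0.3299135994109773,25.86010344912217,2.0,0.29474734278276005,9.457478025315229,42.61658354450525,0.6164575285505955,0.9305443335359803,90.0,0.730700906503932,38.612640590141574,1.0,298.224630745611,0.730700906503932,38.612640590141574
synth-0007-004,16.777549270365107,75.50527204442915,6.65219701977497,11.230363462582066,0.18841797631757867,25.42873345346706,2.0,0.3621543137761893,11.94995846505305,44.569948711824985,0.6420225015319405,0.9163939241339442,90.0,0.7014675365719183,36.50788019168369,1.0,343.975376952363,0.7014675365719183,36.50788019168369
synth-0007-005,22.1869188548857,76.09993192415926,15.646108561537035,8.967040939317457,0.19895100968907445,17.01005652298232,2.0,0.21665340391732976,13.370385130747522,36.97423723712458,0.6648858953353816,0.9541934314475313,90.0,0.7267611481311829,44.44948171144979,1.0,186.9833924995318,0.7267611481311829,44.44948171144979
synth-0007-006,32.09157443577831,65.81839815043708,15.206962532189769,9.924634949683323,0.31849716123568933,21.732570827341693,2.0,0.8678829231213593,12.207858526112403,40.6443175419488,0.6278777097895232,0.9287014361716255,90.0,0.6616432923235694,37.39489212681845,1.0,432.884175637211,0.6616432923235694,37.39489212681845
synth-0007-007,41.28656424327813,78.70920867256385,8.543796407582477,13.476351992137353,0.5563922722884079,24.51854887796899,2.0,0.32310590784176374,9.151751471920559,49.507223530960516,0.44915684088200375,0.9849394893094252,90.0,0.6986641095057772,39.28220246389481,1.0,550.227545486562,0.6986641095057772,39.28220246389481
synth-0007-008,41.184276256943235,73.76842667984104,12.52052810673498,13.902909822897147,0.5725812789215659,18.97579287832917,2.0,0.23573189555724416,13.54589656995275,49.00129088461143,0.4604249112307262,0.873749711526478,90.0,0.6007768298723148,42.529775035977536,1.0,175.48892375299008,0.6007768298723148,42.529775035977536
synth-0007-009,19.102921546277447,76.75614603652741,5.156983086530717,16.152562779950458,0.30856113955671477,22.79846727012807,2.0,0.41941985103455803,12.629247102755436,37.97781721989009,0.49056939307885766,0.8866441329878103,90.0,0.6544690425825528,36.79406027567146,0.9910533201190733,90.0,0.6544690425825528,36.79406027567146
synth-0007-010,43.44372184232444,82.93330870444484,7.986770817896638,11.400680674208399,0.49528800002347356,27.328552869905312,2.0,0.36946749917442817,11.577613345531354,48.44810785574001,0.6084664516104896,0.9145068888323582,90.0,0.7114151127322559,40.80652863852823,1.0,334.27079752793844,0.7114151127322559,40.80652863852823
synth-0007-011,41.34563578254841,76.46584599627553,5.755868873340477,17.227595761684675,0.7122858997715893,20.01995606661628,2.0,0.20465622237870373,10.25499623332379,45.1470679999789,0.7224156589048436,0.9262454687619349,90.0,0.7075628856421684,41.29622182840204,1.0,336.96819462224164,0.7075628856421684,41.29622182840204
synth-0007-012,24.980443776339747,75.93102238717482,5.557744607994976,10.029117522135163,0.2505318063880012,16.98071472965475,2.0,0.4491075856818697,9.562028707462895,42.18794742334437,0.6415116101267462,0.879957521594336,90.0,0.6892027305732418,41.59275006609063,1.0,129.50493920238233,0.6892027305732418,41.59275006609063
synth-0007-013,43.84052534209371,78.633601402445,11.987488022896844,14.28100854864907,0.6260869171877065,16.574451551135677,2.0,0.23763432301556864,12.820150442192343,45.94983873503097,0.7260887153167087,0.9852806611817004,90.0,0.6169807428787835,44.13354861531045,1.0,482.4176376873074,0.6169807428787835,44.13354861531045
synth-0007-014,41.330740999486004,80.93216611900709,5.5131746174927585,17.156354351007323,0.7090848381768884,14.424043675042428,2.0,0.6009454269886488,10.242848866044914,43.505837275780934,0.4750013337423866,0.9841219428510729,90.0,0.6058478761549568,40.90387867834852,1.0,528.8401544071219,0.6058478761549568,40.90387867834852
synth-0007-015,35.336211257019286,60.84301417775564,15.321754155510753,11.10570197053195,0.3924334309882124,21.537549318281425,2.0,0.20659946163683565,12.053753928067632,43.61592122386709,0.476501072033959,0.880757088767817,90.0,0.60595296276885,43.016644050918735,0.9997259079649699,90.0,0.60595296276885,43.016644050918735
synth-0007-016,40.62027214025535,62.02838583864245,8.498035176485105,11.386600833802184,0.46252682462150324,15.57803788412018,2.0,0.2207270232718763,10.56860736001122,46.956903692691945,0.7451236939674939,0.9368885358678039,90.0,0.6193706912211487,42.668591567381554,1.0,305.4243141312956,0.6193706912211487,42.668591567381554
synth-0007-017,20.918477094952394,82.94564717994092,11.702676832418598,14.387499660221028,0.30096458209596894,15.34743948679261,2.0,0.2187326570338905,13.119427445010071,39.907523118989836,0.7214050796521314,0.9267565917913978,90.0,0.7083070999389831,43.67273387572356,1.0,173.60856241092006,0.7083070999389831,43.67273387572356
synth-0007-018,19.845369808409977,61.068094003451385,7.361439000181397,14.508074434222287,0.2879181023550796,21.89193613973897,2.0,0.6515147124314911,10.263872751921534,44.858658699061,0.5826040199847478,0.8808692669478637,90.0,0.6151648451781988,38.80584763500543,0.977768529658813,90.0,0.6151648451781988,38.80584763500543
synth-0007-019,34.87338664842761,93.22210129052735,9.0889634805186,11.768537814087825,0.41040876947732585,21.553303225264084,2.0,0.4547985930521731,10.64926141641207,36.2229719045386,0.582970279255287,0.9961052531103886,90.0,0.7129098204550508,40.790545744292544,1.0,465.5391056644894,0.7129098204550508,40.790545744292544
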