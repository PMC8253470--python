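country,year,ndgm
Pakistan,2005,295320
Pakistan,2006,297535
Pakistan,2007,302502
Pakistan,2008,307896
Pakistan,2009,313753
Pakistan,2010,320113
Pakistan,2011,327019
Pakistan,2012,334517
Pakistan,2013,342660
Pakistan,2014,351502
Pakistan,2015,361102
Pakistan,2016,371527
Pakistan,2017,382847
Pakistan,2018,399214
Pakistan,2019,412578
India,2005,1653599
India,2006,1722462
India,2007,1822164
India,2008,1918236
India,2009,2010811
India,2010,2100015
India,2011,2185971
India,2012,2268798
India,2013,2348609
India,2014,2425515
India,2015,2499621
India,2016,2571028
India,2017,2639836
India,2018,2712540
India,2019,2790214
China,2005,3123852
China,2006,3030930
China,2007,3171122
China,2008,3308158
China,2009,3442107
China,2010,3573039
China,2011,3701023
China,2012,3826124
China,2013,3948408
China,2014,4067937
China,2015,4184775
China,2016,4298982
China,2017,4410616
China,2018,4532154
China,2019,4678514
Kenya,2005,28096
Kenya,2006,28780
Kenya,2007,29338
Kenya,2008,29911
Kenya,2009,30500
Kenya,2010,31104
Kenya,2011,31724
Kenya,2012,32361
Kenya,2013,33015
Kenya,2014,33686
Kenya,2015,34375
Kenya,2016,35083
Kenya,2017,35809
Kenya,2018,36624
Kenya,2019,37652
USA,2005,857472
USA,2006,817100
USA,2007,817591
USA,2008,818325
USA,2009,819425
USA,2010,821073
USA,2011,823541
USA,2012,827238
USA,2013,832776
USA,2014,841071
USA,2015,853496
USA,2016,872107
USA,2017,899984
USA,2018,942407
Sweden,2005,38572
Sweden,2006,38716
Sweden,2007,37881
Sweden,2008,37151
Sweden,2009,36513
Sweden,2010,35955
Sweden,2011,35467
Sweden,2012,35041
Sweden,2013,34668
Sweden,2014,34342
Sweden,2015,34057
Sweden,2016,33808
Sweden,2017,33590
Sweden,2018,33410
Sweden,2019,33521
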