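country,year,deaths
Pakistan,2005,295320
Pakistan,2006,298835
Pakistan,2007,302305
Pakistan,2008,307782
Pakistan,2009,313037
Pakistan,2010,319323
Pakistan,2011,326241
Pakistan,2012,334172
Pakistan,2013,342768
Pakistan,2014,352846
Pakistan,2015,362180
Pakistan,2016,372093
Pakistan,2017,381421
Pakistan,2018,395139
Pakistan,2019,408486
India,2005,1653599
India,2006,1734072
India,2007,1818917
India,2008,1909307
India,2009,1996194
India,2010,2095862
India,2011,2197149
India,2012,2285131
India,2013,2351070
India,2014,2418358
India,2015,2490513
India,2016,2583709
India,2017,2632780
India,2018,2706138
India,2019,2770027
China,2005,3123852
China,2006,3080393
China,2007,3126022
China,2008,3260751
China,2009,3440057
China,2010,3610887
China,2011,3744796
China,2012,3844071
China,2013,3872996
China,2014,4039145
China,2015,4221832
China,2016,4344334
China,2017,4377972
China,2018,4519736
China,2019,4626399
Kenya,2005,28096
Kenya,2006,28709
Kenya,2007,29283
Kenya,2008,29907
Kenya,2009,30578
Kenya,2010,31216
Kenya,2011,31891
Kenya,2012,32452
Kenya,2013,32895
Kenya,2014,33453
Kenya,2015,34203
Kenya,2016,35107
Kenya,2017,35992
Kenya,2018,36555
Kenya,2019,37321
USA,2005,857472
USA,2006,842430
USA,2007,827191
USA,2008,823970
USA,2009,814684
USA,2010,805696
USA,2011,817311
USA,2012,821111
USA,2013,830227
USA,2014,840356
USA,2015,857259
USA,2016,880573
USA,2017,902270
USA,2018,941740
USA,2019,1004285
Sweden,2005,38572
Sweden,2006,38317
Sweden,2007,38053
Sweden,2008,37525
Sweden,2009,36792
Sweden,2010,35644
Sweden,2011,35642
Sweden,2012,35070
Sweden,2013,34559
Sweden,2014,33961
Sweden,2015,33768
Sweden,2016,33710
Sweden,2017,34163
Sweden,2018,33399
Sweden,2019,33233
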