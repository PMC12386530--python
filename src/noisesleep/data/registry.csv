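dataset_id,source,year_start,year_end,sample_size,scale_points,items,two_point_source_selection,top_only
JPN011RT2000,RT,2000,2006,1028,2,sleep_disturbance,true,false
JPN012CR2001,CR,2000,2000,394,5,falling_asleep;awakening,false,false
JPN014CR2002,CR,2002,2002,1483,5,falling_asleep;awakening,false,false
JPN015HR2003,HR,2003,2003,683,5,falling_asleep;awakening,false,false
JPN016RT2003,RT,2003,2004,272,5,falling_asleep;awakening,false,false
JPN017CR2003,CR,2003,2006,712,2,sleep_disturbance,true,false
JPN018HR2003,HR,2003,2006,824,2,sleep_disturbance,true,false
JPN021RT2004,RT,2004,2006,630,5,falling_asleep;awakening,false,false
JPN021CR2004,CR,2004,2006,609,5,falling_asleep;awakening,false,false
JPN022HR2005,HR,2005,2005,110,2,sleep_disturbance,true,false
ISK101RT2007,RT,2007,2007,353,5,falling_asleep;awakening,false,false
KMM102CR2009,CR,2009,2010,242,5,falling_asleep;awakening,false,false
KMM103CR2011,CR,2011,2012,431,5,falling_asleep;awakening,false,false
KMM103HR2011,HR,2011,2012,467,5,falling_asleep;awakening,false,false
STM104RT2011,RT,2011,2011,131,5,falling_asleep;awakening,false,false
STM104CR2011,CR,2011,2011,107,5,falling_asleep;awakening,false,false
NGN105HR2013,HR,2013,2013,224,5,falling_asleep;awakening,false,false
HKR107HR2016,HR,2016,2016,914,5,falling_asleep;awakening,false,false
KMM108CR2016,CR,2016,2016,128,5,falling_asleep;awakening,false,false
KMM108HR2016,HR,2016,2016,422,5,falling_asleep;awakening,false,false
IKF109RT2019,RT,2019,2019,359,2,sleep_disturbance,false,false
KNG110RT2023,RT,2023,2023,260,4,falling_asleep;nocturnal_awakening;early_morning_awakening;poor_sleep;daytime_sleepiness,false,true
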