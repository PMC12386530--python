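# Demographic composition of the analysis sets, by source.
# kind is "gender" or "age_band"; counts are respondents.
source,kind,category,count
RT,gender,male,1399
RT,gender,female,1576
RT,gender,no_answer,58
RT,age_band,under40,424
RT,age_band,40to59,1021
RT,age_band,60plus,1523
RT,age_band,no_answer,65
CR,gender,male,1745
CR,gender,female,2310
CR,gender,no_answer,51
CR,age_band,under40,578
CR,age_band,40to59,1527
CR,age_band,60plus,1964
CR,age_band,no_answer,37
HR,gender,male,1677
HR,gender,female,1926
HR,gender,no_answer,41
HR,age_band,under40,391
HR,age_band,40to59,1180
HR,age_band,60plus,2044
HR,age_band,no_answer,29
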