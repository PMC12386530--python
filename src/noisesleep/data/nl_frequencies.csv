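# Frequency of respondents per 5-dB nighttime noise class (NL), by source,
# for the harmonized Japanese detached-house survey collection (analysis set:
# detached dwellings, Lnight >= 30 dB).
source,nl_center,count
RT,33,27
RT,38,187
RT,43,373
RT,48,621
RT,53,707
RT,58,517
RT,63,330
RT,68,183
RT,73,85
RT,78,3
CR,33,335
CR,38,406
CR,43,693
CR,48,803
CR,53,706
CR,58,579
CR,63,363
CR,68,154
CR,73,58
CR,78,8
HR,33,570
HR,38,1514
HR,43,1196
HR,48,306
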