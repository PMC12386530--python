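# Pooled observed %HSD and sample size per 5-dB nighttime noise class (NL),
# by transportation noise source, for the harmonized Japanese detached-house
# survey collection. Cells with fewer than 50 respondents are not published
# and therefore absent here; the full per-class sample counts (including the
# suppressed classes) live in nl_frequencies.csv, against which each row's n
# cross-checks exactly.
source,nl_center,pct_hsd,n
RT,38,3,187
RT,43,6,373
RT,48,7,621
RT,53,6,707
RT,58,10,517
RT,63,15,330
RT,68,18,183
RT,73,21,85
CR,33,0,335
CR,38,2,406
CR,43,2,693
CR,48,4,803
CR,53,7,706
CR,58,7,579
CR,63,10,363
CR,68,12,154
CR,73,7,58
HR,33,1,570
HR,38,3,1514
HR,43,5,1196
HR,48,5,306
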