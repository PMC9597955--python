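case_id,assessor,final_step,chosen,tool,quality_levels,cochrane,robis,ease_rating,minutes
bakdach-2020,authors,I,Sardana 2018,AMSTAR2,Moderate,no,low_risk,,
bakdach-2020,replication,I,Tasios 2019;Sardana 2019,AMSTAR2,Critically low;,no;no,low_risk;low_risk,,
chalmers-2015,authors,I,Pulavarti 2007,OXMAN_GUYATT,,yes,low_risk,,
chalmers-2015,replication,H,Lenters 2007;Pulavarti 2007,,,no;yes,low_risk;low_risk,,
bolland-2014,authors,NR,Avenell 2009,AMSTAR,High,yes,high_risk,,
bolland-2014,replication,H,Avenell 2009,AMSTAR,High,yes,high_risk,,
grassi-2018,authors,I,He 2011,AMSTAR,High,no,low_risk,,
grassi-2018,replication,H,He 2011,AMSTAR,High,no,low_risk,green,
erickson-2015,authors,NR,Hing 2011,OXMAN_GUYATT,,yes,low_risk,,
erickson-2015,replication,H,Hing 2011,,,yes,low_risk,green,
chen-2019,authors,I,Shen 2017,OXMAN_GUYATT,,no,low_risk,,
chen-2019,replication,H,Dai et al. 2017,,,no,low_risk,green,
chen-2018,authors,I,Feng 2015,AMSTAR,High,no,high_risk,,
chen-2018,replication,I,Feng 2015,AMSTAR,High,no,high_risk,yellow,
xu-2017,authors,H,Lenza 2015;Hussain 2016,AMSTAR,Highest;High,yes;no,low_risk;high_risk,,
xu-2017,replication,H,Lenza 2015;Hussain 2016,AMSTAR,Highest;High,yes;no,low_risk;high_risk,green,
song-2016,authors,H,Cao 2015;Wu 2015,AMSTAR,High;High,no;no,high_risk;low_risk,,
song-2016,replication,H,Gurusamy 2013,AMSTAR,Highest,yes,low_risk,green,
zhao-2015a,authors,H,Lenza 2013,AMSTAR,High,yes,low_risk,,
zhao-2015a,replication,H,Lenza 2013,AMSTAR,High,yes,low_risk,green,
tan-2018,authors,H,Feng 2015,AMSTAR,High,no,low_risk,,
tan-2018,replication,H,Lin 2013,AMSTAR,High,no,high_risk,green,
poolman-2007,authors,F,Biau 2006,OXMAN_GUYATT,,no,low_risk,,
poolman-2007,replication,H,Biau 2006,,,no,low_risk,green,
mascarenhas-2014,authors,I,Millett 2014,OXMAN_GUYATT,,no,low_risk,,
mascarenhas-2014,replication,H,Sheibani-Rad 2013,,,no,high_risk,yellow,
xing-2016,authors,I,Bellamy 2006,AMSTAR,Highest,yes,high_risk,,
xing-2016,replication,H,Richette 2015;Bellamy 2006,AMSTAR,High;Highest,no;yes,high_risk;high_risk,yellow,
mascarenhas-2015,authors,I,Li 2014;van Eck 2012;Tiamklang 2012,OXMAN_GUYATT,,no;yes;no,low_risk;low_risk;low_risk,,
mascarenhas-2015,replication,H,Li 2014;van Eck 2012;Tiamklang 2012,,,no;yes;no,low_risk;low_risk;low_risk,yellow,
guo-2018,authors,I,Xia 2014,AMSTAR,Moderate,no,high_risk,,
guo-2018,replication,H,Hu 2011,AMSTAR,Low,no,low_risk,red,
houck-2017,authors,I,Riboh 2014,OXMAN_GUYATT,,no,low_risk,,
houck-2017,replication,H,Chan 2014,,,no,high_risk,yellow,
pekala-2019,authors,I,Pabalan 2016,AMSTAR,Moderate,no,high_risk,,
pekala-2019,replication,I,Nong 2016;Pabalan 2016,AMSTAR,Moderate;Moderate,no;no,low_risk;high_risk,yellow,
zhiyong-2019,authors,I,Sun et al. 2016,AMSTAR,Moderate,no,low_risk,,
zhiyong-2019,replication,I,Feng 2015,AMSTAR,Moderate,no,low_risk,red,
fu-2019,authors,H,Rabi et al. 2015,AMSTAR,High,no,high_risk,,
fu-2019,replication,H,Handoll 2012,AMSTAR,Highest,yes,low_risk,green,
zhao-2015b,authors,I,Ouyang 2013,AMSTAR,Moderate,no,low_risk,,
zhao-2015b,replication,H,Heineman 2010,AMSTAR,Moderate,no,low_risk,green,
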