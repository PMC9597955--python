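case_id,assessor,review_label,cochrane,robis,measure,point,ci_low,ci_high,p_value,verdict,direction
bakdach-2020,authors,Sardana 2018,no,low_risk,RR,0.39,0.26,0.59,0.005,favourable,disagree
bakdach-2020,replication,Tasios 2019,no,low_risk,RR,0.46,0.18,1.15,0.1,null,disagree
chalmers-2015,authors,Pulavarti 2007,yes,low_risk,RR,0.89,0.09,8.72,0.92,null,agree
chalmers-2015,replication,Lenters 2007,no,low_risk,RR,1.31,0.51,3.34,0.58,null,agree
chen-2019,authors,Shen 2017,no,low_risk,MD,-17.39,-22.32,-12.46,<0.00001,favourable,agree
chen-2019,replication,Dai et al. 2017,no,low_risk,MD,-2.83,-4.26,-1.39,0.0001,favourable,agree
fu-2019,authors,Rabi et al. 2015,no,high_risk,MD,1.63,-2.84,6.11,0.47,null,agree
fu-2019,replication,Handoll 2012,yes,low_risk,MD,2.36,-3.52,8.24,0.43,null,agree
guo-2018,authors,Xia 2014,no,high_risk,RR,1.19,1.05,1.35,0.006,favourable,agree
guo-2018,replication,Hu 2011,no,low_risk,OR,3.34,1.92,5.81,<0.0001,favourable,agree
houck-2017,authors,Riboh 2014,no,low_risk,MD,14.70,5.52,23.87,0.002,favourable,agree
houck-2017,replication,Chan 2014,no,high_risk,MD,1.05,0.03,2.06,0.04,favourable,agree
mascarenhas-2014,authors,Millett 2014,no,low_risk,MD,-3.7,-8.8,1.4,0.16,null,agree
mascarenhas-2014,replication,Sheibani-Rad 2013,no,high_risk,MD,0.159,-0.08,0.40,0.255,null,agree
pekala-2019,authors,Pabalan 2016,no,high_risk,OR,0.99,0.75,1.31,0.95,null,agree
pekala-2019,replication,Nong 2016,no,low_risk,OR,1.13,0.76,1.69,0.55,null,agree
song-2016,authors,Cao 2015,no,high_risk,RR,0.41,0.07,2.52,0.34,null,agree
song-2016,authors,Wu 2015,no,low_risk,RR,0.98,0.2,4.75,0.98,null,agree
song-2016,replication,Gurusamy 2013,yes,low_risk,OR,0.49,0.05,4.72,0.54,null,agree
tan-2018,authors,Feng 2015,no,low_risk,MD,-0.18,-0.36,-0.00,0.04,favourable,disagree
tan-2018,replication,Lin 2013,no,high_risk,MD,0.05,-0.49,0.59,0.87,null,disagree
xing-2016,authors,Bellamy 2006,yes,high_risk,MD,-13.00,-17.77,-8.33,<0.00001,favourable,agree
xing-2016,replication,Richette 2015,no,high_risk,SMD,-0.21,-0.32,-0.1,NR,favourable,agree
zhao-2015b,authors,Ouyang 2013,no,low_risk,RR,1.20,0.63,2.28,0.58,null,agree
zhao-2015b,replication,Heineman 2010,no,low_risk,RR,0.71,0.28,1.76,0.45,null,agree
zhiyong-2019,authors,Sun et al. 2016,no,low_risk,MD,-0.12,-0.33,0.09,0.28,null,disagree
zhiyong-2019,replication,Feng 2015,no,low_risk,MD,-0.18,-0.36,-0.00,0.04,favourable,disagree
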