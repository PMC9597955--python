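case_id,label,primary_outcome,primary_intervention,benefit_direction,n_reviews,same_criteria_judged,pilot,country,n_authors
bakdach-2020,Bakdach 2020,Incidence of white spot lesions,Topical fluoride toothpaste and/or brush on gel or foam,lower_better,3,no,yes,Syria,2
chalmers-2015,Chalmers 2015,Rate of recurrent instability,Arthroscopic versus open shoulder stabilization,lower_better,2,yes,yes,USA,7
bolland-2014,Bolland 2014,Hip fracture,Vitamin D with or without calcium versus placebo,lower_better,4,yes,yes,New Zealand,2
grassi-2018,Grassi 2018,Re-operation rate,Patellar resurfacing versus non-resurfacing,lower_better,5,yes,no,Italy,8
erickson-2015,Erickson 2015,Recurrent patellar dislocation,Operative versus non-operative treatment,lower_better,2,yes,no,USA,8
chen-2019,Chen P 2019,Pain (WOMAC total score),PRP injection versus hyaluronic acid or placebo,lower_better,4,yes,no,China,8
chen-2018,Chen X 2018,Short-term VAS pain,Unilateral versus bilateral percutaneous kyphoplasty,lower_better,5,no,no,China,10
xu-2017,Xu 2017,Fracture non-union,Intramedullary fixation versus plate fixation,lower_better,5,yes,no,China,7
song-2016,Song 2016,Bile duct injury,Early versus delayed laparoscopic cholecystectomy,lower_better,6,yes,no,China,6
zhao-2015a,Zhao 2015a,Constant score,Surgical versus conservative treatment,higher_better,3,yes,no,China,3
poolman-2007,Poolman 2007,Knee stability (pivot shift test),Hamstring versus bone-patellar tendon-bone autograft,higher_better,3,yes,no,Canada,4
mascarenhas-2014,Mascarenhas 2014,Constant score,Single-row versus double-row rotator cuff repair,higher_better,3,yes,no,USA,7
tan-2018,Tan 2018,Short-term VAS pain,Unilateral versus bilateral percutaneous kyphoplasty,lower_better,6,yes,no,China,6
xing-2016,Xing 2016,Early and late knee pain,Hyaluronic acid versus placebo,lower_better,10,yes,no,China,7
mascarenhas-2015,Mascarenhas 2015,Knee stability (pivot-shift test),Single-bundle versus double-bundle ACL reconstruction,higher_better,6,yes,no,USA,7
houck-2017,Houck 2017,Range of motion,Early versus delayed motion rehabilitation,higher_better,5,yes,no,USA,5
pekala-2019,Pekala 2019,Intervertebral disc degeneration,FokI polymorphism,lower_better,7,no,no,Poland,7
zhiyong-2019,Zhiyong 2019,Short-term VAS pain,Unilateral versus bilateral balloon kyphoplasty,lower_better,6,no,no,China,5
fu-2019,Fu 2019,Constant score,Surgical versus non-surgical treatment,higher_better,4,yes,no,China,4
zhao-2015b,Zhao 2015b,Fracture non-union,Intramedullary nail versus plate fixation,lower_better,4,yes,no,China,4
guo-2018,Guo 2018,Disease control rate,Shenyi capsule plus chemotherapy versus chemotherapy alone,higher_better,4,yes,no,China,5
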