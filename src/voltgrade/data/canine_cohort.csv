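case_id,age_years,breed,weight_kg,staging,diagnosis,grade,siln_metastasis,muc1_score,is_control
1,13,Mix,20,R5/T1N0M0,Carcinoma-solid type,3,0,0,0
2,13,Italian Greyhound,30,R3/T1N0M0,Carcinoma-mixed type,1,0,1,0
3,10,Mix,17,R4/T2N1M0,Carcinoma-simple (tubular),2,1,0,0
4,12,Border Terrier,12,L3/T1N0M0,Carcinoma-mixed type,2,0,1,0
5,12,Boxer,27,L5/T2N0M0,Adenosquamous carcinoma,3,0,0,0
6,12,American Cocker Spaniel,12,L5/T2N1M1,Sarcoma,3,1,0,0
7,11,Mix,23,R5/T1N0M0,Carcinoma-complex type,2,0,1,0
8,8,Golden Retriever,27,L4/T1N0M0,Carcinoma-simple (tubulopapillary),2,0,2,0
9,11,Mix,25,L5/T2N1M1,Carcinoma-simple (tubulopapillary),3,1,0,0
10,13,Golden Retriever,28,L4/T1N0M0,Carcinoma-complex type,2,0,1,0
11,10,Mix,12,R5/T1N0M0,Carcinoma-simple (tubulopapillary),2,0,1,0
12,11,Yorkshire Terrier,6,L4/T1N1M0,Carcinoma-complex type,2,1,1,0
13,8,American Cocker Spaniel,12,R5/T2N0M0,Carcinoma-solid type,3,0,1,0
14,11,Cavalier King Charles Spaniel,8,L4/T2N1M0,Carcinoma-simple (tubulopapillary),3,1,3,0
15,13,Border Terrier,7,L5/T1N0M0,Carcinoma-simple (tubular),3,0,1,0
16,10,American Cocker Spaniel,22,R5/T1N1M0,Intraductal papillary carcinoma,1,1,0,0
17,12,Mix,10,R3/T1N0M0,Carcinoma-mixed type,2,0,3,0
18,4,Cocker Spaniel,20,R5/-,Mild hyperplastic and fibrous reactions,,0,,1
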