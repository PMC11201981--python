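age,laterality,quadrant,density,histology,grade,actual_size_cm,estimated_size_cm,dcis_lcis,staging,er,pr,her2,depth_mri_cm
68,L,UOQ,SF,ADH,X,0.5,1,None,,,,,2.91
60,R,UOQ,HD,DCIS,2,1.4,1.3,DCIS,T1c N0 Mx,+,+,,1.18
71,R,UOQ,PF,IDC,1,0.9,1,None,T1c N0 Mx,+,-,1+,2.26
67,L,UIQ,ED,IDC,1,1.7,1.9,None,T1c N0 Mx,+,+,1+,2.4
67,L,UOQ,SF,IDC,1,1.1,1.2,None,T1c N0 Mx,+,+,2+,2.28
48,R,UOQ,SF,IDC,1,1.1,1,DCIS,T1c N0 Mx,+,+,1+,2.23
64,R,UOQ,SF,IDC,1,1.2,1,None,T1c N0 Mx,+,+,1+,4.95
65,L,UOQ,HD,IDC,1,1.6,1.4,None,T1c N0 Mx,+,+,1+,
70,R,UOQ,SF,IDC,2,0.8,1,DCIS,T1c N0 Mx,+,+,1+,2.14
51,L,UOQ,SF,IDC,2,1.9,1.9,LCIS,T2 N1a M0,+,+,1+,0.95
46,R,LIQ,HD,IDC,2,1.1,1.5,DCIS,T1c N0 Mx,+,+,1+,2.96
72,R,UOQ,SF,IDC,2,1.1,1,DCIS,T1c N0 Mx,+,+,2+,2.74
64,L,UOQ,PF,IDC,2,1.5,1,DCIS,T1c N1a M0,+,+,2+,2.93
63,L,UIQ,SF,IDC,2,0.5,1,DCIS,T1b N0 Mx,+,+,0+,3.9
57,L,UIQ,SF,IDC,2,1.2,1,None,T1c N0 Mx,+,+,2+,2
52,R,UOQ,SF,IDC,3,1.2,1,DCIS,T1a N0 Mx,,,0+,5.45
68,R,UOQ,SF,IDC,3,2.7,2.7,DCIS,T2 N1a Mx,+,+,1+,2.72
68,L,UOQ,HD,IDC,3,1.3,1,None,T2 N0 Mx,,,0+,2.43
70,R,LIQ,SF,IDC,3,0.5,1,DCIS,T1b N0 Mx,,,0+,3.76
42,R,UOQ,HD,IDC,3,0.5,1,DCIS,T1b N0 Mx,,,0+,2.42
49,R,LOQ,SF,IDC,3,2.6,2.7,DCIS,T2 N0 Mx,,,0+,4.3
72,L,UIQ,SF,IDC,3,0.9,1,DCIS,T1b N0 Mx,,,0+,1.14
68,L,UOQ,SF,ILC,1,0.8,1,DCIS,T1c N1a M0,+,+,1+,2.93
70,L,UOQ,SF,ILC,2,2.1,2.3,LCIS,T2 N0 Mx,+,+,2+,2.27
67,L,UIQ,SF,LCIS,X,0.5,1,LCIS,,,,,1.29
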