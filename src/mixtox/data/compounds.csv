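id,name,cas,smiles,group,neg_log_ec50_exp,neg_log_ec50_pred,residual
1#,Acetaldehyde,75-07-0,CC=O,aldehyde,2.36,3.177,0.817
2#,Propanal,123-38-6,CCC=O,aldehyde,2.72,3.212,0.492
3#,Butyraldehyde,123-72-8,CCCC=O,aldehyde,3.25,3.224,-0.0265
4#,Valeraldehyde,110-62-3,CCCCC=O,aldehyde,3.27,3.628,0.358
5#,Benzaldehyde,100-52-7,O=Cc1ccccc1,aldehyde,3.43,4.552,1.122
6#,p-Nitrobenzaldehyde,555-16-8,O=Cc1ccc(cc1)[N+](=O)[O-],aldehyde,4.28,3.634,-0.646
7#,p-Terephthaldehyde,623-27-8,O=Cc1ccc(C=O)cc1,aldehyde,4.07,4.880,0.810
8#,p-Chlorobenzaldehyde,104-88-1,O=Cc1ccc(Cl)cc1,aldehyde,3.97,3.876,-0.094
9#,p-Bromobenzaldehyde,1122-91-4,O=Cc1ccc(Br)cc1,aldehyde,4.3,3.861,-0.437
10#,p-Hydroxybenzaldehyde,123-08-0,O=Cc1ccc(O)cc1,aldehyde,4.54,3.777,-0.763
11#,p-Methyl benzaldehyde,104-87-0,Cc1ccc(C=O)cc1,aldehyde,3.82,4.030,0.210
12#,p-Methoxybenzaldehyde,123-11-5,COc1ccc(C=O)cc1,aldehyde,4.03,3.985,-0.0448
13#,p-Dimethylaminobenzaldehyde,100-10-7,CN(C)c1ccc(C=O)cc1,aldehyde,5.4,4.622,-0.778
14#,Malononitrile,109-77-3,N#CCC#N,cyanogenic,2.55,1.783,-0.767
15#,Glycolonitrile,107-16-4,OCC#N,cyanogenic,2.98,2.141,-0.839
16#,alpha-Hydroxyisobutyronitrile,75-86-5,CC(C)(O)C#N,cyanogenic,3.61,3.834,0.227
17#,Allyl cyanide,109-75-1,C=CCC#N,cyanogenic,2.06,1.507,-0.553
18#,Benzonitrile,100-47-0,N#Cc1ccccc1,cyanogenic,3.48,3.456,-0.0237
19#,Benzyl cyanide,140-29-4,N#CCc1ccccc1,cyanogenic,4.23,2.963,-1.267
20#,Acetonitrile,75-05-8,CC#N,cyanogenic,0.75,2.023,1.273
21#,Acrylonitrile,107-13-1,C=CC#N,cyanogenic,1.51,1.467,-0.0414
22#,Succinonitrile,110-61-2,N#CCCC#N,cyanogenic,0.36,2.401,2.042
23#,Phthalonitrile,91-15-6,N#Cc1ccccc1C#N,cyanogenic,3.51,2.622,-0.888
24#,Lactonitrile,78-97-7,CC(O)C#N,cyanogenic,2.01,2.440,0.430
25#,Atrazine,1912-24-9,CCNc1nc(Cl)nc(NC(C)C)n1,triazine,6.68,7.543,0.863
26#,Prometryn,7287-19-6,CSc1nc(NC(C)C)nc(NC(C)C)n1,triazine,8.07,6.457,-1.613
27#,Simetryn,1014-70-6,CCNc1nc(NCC)nc(SC)n1,triazine,6.29,5.565,-0.725
28#,Prometone,1610-18-0,COc1nc(NC(C)C)nc(NC(C)C)n1,triazine,8.99,7.801,-1.182
29#,Simazine,122-34-9,CCNc1nc(Cl)nc(NCC)n1,triazine,5.43,6.892,1.462
30#,Metribuzin,21087-64-9,CC(C)(C)C1=NN=C(SC)N(N)C1=O,triazine,5.7,6.873,1.173
31#,Cyanazine,21725-46-2,CCNc1nc(Cl)nc(NC(C)(C)C#N)n1,triazine,6.61,6.631,0.0212
32#,Terbutryn,886-50-0,CCNc1nc(NC(C)(C)C)nc(SC)n1,triazine,7.95,6.131,-1.819
33#,Terbutylazine,5915-41-3,CCNc1nc(Cl)nc(NC(C)(C)C)n1,triazine,6.93,8.225,1.295
34#,Ametryn,834-12-8,CCNc1nc(NC(C)C)nc(SC)n1,triazine,6.56,5.516,-1.044
35#,Diuron,330-54-1,CN(C)C(=O)Nc1ccc(Cl)c(Cl)c1,urea,7.72,6.065,-1.655
36#,Chlorotoluron,15545-48-9,CN(C)C(=O)Nc1ccc(C)c(Cl)c1,urea,8.4,5.898,-2.502
37#,Monolinuron,1746-81-2,CON(C)C(=O)Nc1ccc(Cl)cc1,urea,7.33,6.384,-0.946
38#,Monuron,150-68-5,CN(C)C(=O)Nc1ccc(Cl)cc1,urea,6.3,6.254,-0.0460
39#,Methabenzthiazuron,18691-97-9,CNC(=O)N(C)c1nc2ccccc2s1,urea,7.02,6.022,-0.998
40#,Isoproturon,34123-59-6,CC(C)c1ccc(NC(=O)N(C)C)cc1,urea,7.18,6.554,-0.627
41#,Fenuron,101-42-8,CN(C)C(=O)Nc1ccccc1,urea,7.33,6.665,-0.665
42#,Ethametsulfuron,111353-84-5,CCOc1nc(NC)nc(NC(=O)NS(=O)(=O)c2ccccc2C(=O)OC)n1,urea,4.13,6.302,2.172
43#,Chlorsulfuron,64902-72-3,COc1nc(C)nc(NC(=O)NS(=O)(=O)c2ccccc2Cl)n1,urea,6.42,6.337,-0.0833
44#,Metsulfuron,79510-48-8,COc1nc(C)nc(NC(=O)NS(=O)(=O)c2ccccc2C(=O)O)n1,urea,6.29,6.245,-0.0447
45#,Sulfamethazine,57-68-1,Cc1cc(C)nc(NS(=O)(=O)c2ccc(N)cc2)n1,sulfonamide,4.08,5.506,1.426
46#,Sulfapyridine,144-83-2,Nc1ccc(cc1)S(=O)(=O)Nc1ccccn1,sulfonamide,3.84,3.407,-0.433
47#,Sulfamethoxazole,723-46-6,Cc1cc(NS(=O)(=O)c2ccc(N)cc2)no1,sulfonamide,4.45,4.511,0.0609
48#,Sulfadiazine,68-35-9,Nc1ccc(cc1)S(=O)(=O)Nc1ncccn1,sulfonamide,4.5,5.021,0.521
49#,Sulfisoxazole,127-69-5,Cc1noc(NS(=O)(=O)c2ccc(N)cc2)c1C,sulfonamide,4.43,5.506,1.076
50#,Sulfamonomethoxine,1220-83-3,COc1cc(NS(=O)(=O)c2ccc(N)cc2)ncn1,sulfonamide,5.05,4.535,-0.515
51#,Sulfachloropyridazine,80-32-0,Nc1ccc(cc1)S(=O)(=O)Nc1ccc(Cl)nn1,sulfonamide,4.78,5.117,0.337
52#,Sulfachinoxalin,59-40-5,Nc1ccc(cc1)S(=O)(=O)Nc1cnc2ccccc2n1,sulfonamide,4.53,5.203,0.673
53#,Sulfamethoxydiazine,651-06-9,COc1cnc(NS(=O)(=O)c2ccc(N)cc2)nc1,sulfonamide,4.41,5.050,0.640
54#,Sulfamethoxypyridazine,80-35-3,COc1ccc(NS(=O)(=O)c2ccc(N)cc2)nn1,sulfonamide,4.36,4.934,0.579
55#,Trimethoprim,738-70-5,COc1cc(Cc2cnc(N)nc2N)cc(OC)c1OC,trimethoprim,3.22,5.209,1.989
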