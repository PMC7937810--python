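# Published group reference distributions for hippocampal volumetry.
# One row per (method, region, group). method: FS = FreeSurfer v6.0 (Ex-vivo atlas,
# whole hippocampus + 12 subfields), vB = volBrain-HIPS (Winterburn atlas, whole
# hippocampus + 5 subfield groupings). group: HC = healthy controls (n=61),
# RHS = right hippocampal sclerosis (n=22), LHS = left hippocampal sclerosis (n=35).
# abs columns: group mean and 95% CI of absolute volume in mm3 (informational only;
# for the smallest FS subfields the printed absolute scale conflicts with the %TIV
# columns, which are canonical throughout this package).
# pct columns: group mean and 95% CI of volume as percent of total intracranial volume.
# asym columns: group mean and 95% CI of the per-subject right-left asymmetry index (%),
# positive = right larger.
method,region,group,n,right_abs_mm3,right_abs_lo,right_abs_hi,left_abs_mm3,left_abs_lo,left_abs_hi,right_pct_mean,right_pct_lo,right_pct_hi,left_pct_mean,left_pct_lo,left_pct_hi,asym_mean,asym_lo,asym_hi
vB,Hippocampus,HC,61,2408,2326,2490,2320,2246,2394,0.1750,0.1713,0.1787,0.1686,0.1653,0.1720,3.6,2.2,5.0
vB,Hippocampus,RHS,22,1429,1295,1563,2293,2138,2461,0.1073,0.0979,0.1167,0.1727,0.1614,0.1840,-47.4,-53.2,-41.6
vB,Hippocampus,LHS,35,2460,2331,2590,1437,1324,1549,0.1810,0.1723,0.1896,0.1055,0.0981,0.1129,53.2,48.0,58.3
vB,CA1,HC,61,808.4,777.2,839.6,783.4,754.1,812.7,0.0587,0.0571,0.0603,0.0569,0.0554,0.0584,3.0,0.8,5.3
vB,CA1,RHS,22,477.6,426.2,529.0,801.6,740.0,863.1,0.0359,0.0320,0.0398,0.0603,0.0555,0.0651,-51.6,-58.5,-44.8
vB,CA1,LHS,35,852.4,800.9,904.0,487.2,445.4,529.0,0.0626,0.0592,0.0660,0.0357,0.0330,0.0384,55.1,49.3,60.9
vB,CA2-CA3,HC,61,186.4,177.5,195.3,150.4,149.8,158.9,0.0135,0.0129,0.0141,0.0109,0.0103,0.0114,21.7,16.8,26.7
vB,CA2-CA3,RHS,22,92.4,78.6,106.3,149.0,131.8,166.3,0.0069,0.0059,0.0079,0.0112,0.0099,0.0124,-47.8,-62.5,-33.0
vB,CA2-CA3,LHS,35,196.0,180.3,211.7,82.1,72.7,91.6,0.0143,0.0133,0.0154,0.0060,0.0053,0.0066,82.2,73.9,90.4
vB,CA4-DG,HC,61,651.8,624.1,679.6,599.6,576.4,622.8,0.0472,0.0459,0.0486,0.0435,0.0424,0.0469,8.1,5.7,10.0
vB,CA4-DG,RHS,22,379.2,333.4,425.0,599.9,551.1,648.8,0.0284,0.0252,0.0317,0.0450,0.0418,0.0481,-46.3,-55.2,-37.4
vB,CA4-DG,LHS,35,643.8,606.6,681.0,356.6,319.3,394.0,0.0473,0.0448,0.0499,0.0261,0.0236,0.0286,59.1,51.7,66.6
vB,SR-SL-SM,HC,61,482.8,464.9,500.6,478.0,462.3,493.7,0.0350,0.0342,0.0358,0.0347,0.0339,0.0355,0.7,-0.9,2.5
vB,SR-SL-SM,RHS,22,276.1,240.9,311.3,475.4,440.5,510.4,0.0206,0.0182,0.0230,0.0357,0.0332,0.0382,-55.0,-64.6,-45.4
vB,SR-SL-SM,LHS,35,502.3,474.2,530.3,281.9,254.4,309.5,0.0370,0.0349,0.0390,0.0207,0.0188,0.0227,57.8,51.0,54.5
vB,Subiculum,HC,61,279.2,268.6,289.9,308.5,296.1,320.1,0.0203,0.0196,0.0211,0.0225,0.0216,0.0233,-9.9,-12.4,-7.4
vB,Subiculum,RHS,22,204.2,184.8,223.7,271.1,251.5,290.7,0.0153,0.0140,0.0165,0.0204,0.0189,0.0218,-28.6,-35.8,-21.3
vB,Subiculum,LHS,35,266.2,250.6,281.9,229.0,214.3,243.8,0.0196,0.0184,0.0207,0.0168,0.0158,0.0179,15.3,9.9,20.6
FS,Hippocampus,HC,61,3454,3355,3554,3398,3300,3496,0.2239,0.2196,0.2283,0.2203,0.2158,0.2248,1.6,0.5,2.7
FS,Hippocampus,RHS,22,2578,2401,2755,3386,3204,3568,0.1743,0.1603,0.1882,0.2289,0.2134,0.2444,-27.4,-31.4,-23.5
FS,Hippocampus,LHS,35,3570,3404,3737,2560,2425,2696,0.2358,0.2257,0.2459,0.1693,0.1604,0.1783,33.0,28.2,37.7
FS,CA1,HC,61,634,611,657,615,594,636,0.0411,0.0400,0.0421,0.0398,0.0388,0.0408,3.0,1.2,4.8
FS,CA1,RHS,22,483,442,524,636,587,685,0.0326,0.0296,0.0357,0.0428,0.0397,0.0460,-27.6,-33.2,-22.0
FS,CA1,LHS,35,680,645,715,465,435,494,0.0449,0.0428,0.0471,0.0307,0.0288,0.0326,37.8,33.1,42.6
FS,CA3,HC,61,217,208,225,190,183,197,0.0140,0.0136,0.0145,0.0123,0.0119,0.0127,13.1,10.3,16.0
FS,CA3,RHS,22,157,144,171,194,182,207,0.0106,0.0097,0.0115,0.0132,0.0121,0.0143,-21.6,-28.2,-15.0
FS,CA3,LHS,35,232,218,246,149,139,159,0.0152,0.0144,0.0161,0.0098,0.0092,0.0104,43.4,37.7,49.1
FS,CA4,HC,61,260,252,268,245,237,252,0.0168,0.0164,0.0172,0.0159,0.0154,0.0163,5.9,4.0,7.8
FS,CA4,RHS,22,182,166,198,248,235,261,0.0123,0.0111,0.0134,0.0168,0.0155,0.0181,-31.5,-37.4,-25.6
FS,CA4,LHS,35,272,258,287,174,162,186,0.0180,0.0171,0.0188,0.0115,0.0107,0.0123,43.9,37.1,50.7
FS,Presubiculum,HC,61,298,288,307,324,313,335,0.0193,0.0188,0.0198,0.0210,0.0204,0.0215,-8.3,-10.1,-6.5
FS,Presubiculum,RHS,22,223,207,239,303,285,320,0.0150,0.0138,0.0163,0.0204,0.0191,0.0218,-30.6,-36.6,-24.7
FS,Presubiculum,LHS,35,293,280,305,243,229,258,0.0194,0.0185,0.0203,0.0161,0.0151,0.0171,19.0,13.8,24.1
FS,Subiculum,HC,61,429,416,443,432,417,446,0.0278,0.0272,0.0285,0.0280,0.0273,0.0286,-0.4,-2.1,1.2
FS,Subiculum,RHS,22,325,298,351,436,408,464,0.0219,0.0200,0.0237,0.0294,0.0273,0.0316,-29.7,-34.2,-25.3
FS,Subiculum,LHS,35,434,414,453,333,316,350,0.0286,0.0274,0.0299,0.0220,0.0209,0.0232,26.1,21.4,30.8
FS,Parasubiculum,HC,61,580,560,610,610,580,630,0.0038,0.0036,0.0039,0.0039,0.0038,0.0041,-3.9,-7.6,-0.1
FS,Parasubiculum,RHS,22,470,430,510,560,520,610,0.0032,0.0029,0.0035,0.0038,0.0035,0.0041,-17.9,-24.4,-11.4
FS,Parasubiculum,LHS,35,580,550,620,520,470,570,0.0039,0.0036,0.0041,0.0034,0.0031,0.0037,12.4,5.1,19.8
FS,Tail,HC,61,539,519,558,543,525,562,0.0349,0.0338,0.0360,0.0353,0.0342,0.0363,-0.9,-3.4,1.4
FS,Tail,RHS,22,396,366,426,524,483,565,0.0268,0.0244,0.0292,0.0355,0.0320,0.0390,-27.6,-31.3,-23.8
FS,Tail,LHS,35,544,513,575,399,376,423,0.0359,0.0340,0.0378,0.0265,0.0248,0.0282,30.0,25.4,35.5
FS,Fissure,HC,61,148,142,154,140,133,146,0.0096,0.0092,0.0100,0.0090,0.0087,0.0094,6.0,2.6,9.3
FS,Fissure,RHS,22,140,126,154,142,128,155,0.0094,0.0085,0.0103,0.0096,0.0086,0.0105,-1.1,-7.4,5.1
FS,Fissure,LHS,35,152,142,161,139,129,148,0.0100,0.0095,0.0105,0.0091,0.0086,0.0097,8.9,2.0,15.9
FS,Molecular_layer,HC,61,573,555,591,560,543,577,0.0371,0.0363,0.0380,0.0363,0.0355,0.0372,2.2,0.9,3.5
FS,Molecular_layer,RHS,22,424,392,456,562,531,593,0.0286,0.0263,0.0310,0.0380,0.0354,0.0406,-28.4,-33.1,-23.7
FS,Molecular_layer,LHS,35,596,567,625,419,395,444,0.0393,0.0375,0.0411,0.0277,0.0261,0.0293,34.8,29.9,39.7
FS,GC-ML-DG,HC,61,302,293,312,287,277,296,0.0196,0.0191,0.0201,0.0186,0.0181,0.0191,5.4,3.7,7.1
FS,GC-ML-DG,RHS,22,213,195,231,288,272,303,0.0144,0.0130,0.0158,0.0195,0.0180,0.0210,-30.6,-35.9,-25.2
FS,GC-ML-DG,LHS,35,318,301,335,205,192,219,0.0210,0.0199,0.0220,0.0135,0.0127,0.0144,43.0,36.6,49.5
FS,Fimbria,HC,61,810,750,860,810,760,860,0.0052,0.0049,0.0054,0.0052,0.0049,0.0055,-0.2,-5.2,4.6
FS,Fimbria,RHS,22,710,630,790,770,670,860,0.0048,0.0041,0.0056,0.0052,0.0045,0.0059,-7.2,-15.0,0.5
FS,Fimbria,LHS,35,750,690,810,650,600,710,0.0049,0.0046,0.0053,0.0043,0.0039,0.0047,14.2,7.4,21.0
FS,HATA,HC,61,590,560,610,570,540,590,0.0038,0.0036,0.0039,0.0036,0.0035,0.0038,3.4,0.3,6.5
FS,HATA,RHS,22,520,470,570,570,520,620,0.0035,0.0031,0.0039,0.0038,0.0035,0.0042,-8.4,-17.2,0.4
FS,HATA,LHS,35,630,600,660,500,470,530,0.0042,0.0039,0.0044,0.0033,0.0031,0.0035,23.8,16.6,31.1
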