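alternative,model,C1,C2,C3,C4,C5,C6,C7
A1,ReF-decision tree,0.37700,0.00001,0.99312,0.98943,0.98943,0.98944,0.98943
A2,ReF-SVM,2.22900,0.91700,0.95052,0.83245,0.83251,0.83266,0.83245
A3,ReF-naive Bayes,0.13400,0.05000,0.96142,0.84415,0.84367,0.84344,0.84415
A4,ReF-KNN,0.68700,0.51000,0.90306,0.76038,0.74901,0.75549,0.76038
A5,ReF-AdaBoost,0.57700,0.28700,0.98897,0.98528,0.98528,0.98530,0.98528
A6,IG-decision tree,0.47200,0.00200,0.99312,0.98943,0.98943,0.98944,0.98943
A7,IG-SVM,2.70600,0.91400,0.94778,0.83358,0.83364,0.83401,0.83358
A8,IG-naive Bayes,0.21900,0.04000,0.96313,0.84113,0.84029,0.83988,0.84113
A9,IG-KNN,0.60900,0.60600,0.89653,0.75585,0.74503,0.74750,0.75585
A10,IG-AdaBoost,0.69700,0.37600,0.98642,0.98189,0.98189,0.98193,0.98189
A11,Chi2-decision tree,0.46600,0.00200,0.99271,0.98830,0.98830,0.98830,0.98830
A12,Chi2-SVM,3.19100,1.06000,0.94979,0.83094,0.83080,0.83066,0.83094
A13,Chi2-naive Bayes,0.22900,0.04300,0.96235,0.84075,0.83966,0.83926,0.84075
A14,Chi2-KNN,0.90700,0.62900,0.89462,0.74302,0.73201,0.73414,0.74302
A15,Chi2-AdaBoost,0.75400,0.59500,0.98670,0.98226,0.98226,0.98230,0.98226
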