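mechanism,criterion,rank,method
MCAR,accuracy,1,forest
MCAR,accuracy,2,iterative_pca
MCAR,accuracy,3,svd
MCAR,accuracy,4,knn
MCAR,accuracy,5,mean
MCAR,accuracy,6,median
MCAR,accuracy,7,min
MCAR,accuracy,8,qrilc
MCAR,accuracy,9,half_min
MCAR,accuracy,10,zero
MCAR,accuracy,11,random
MCAR,speed,1,min
MCAR,speed,2,half_min
MCAR,speed,3,median
MCAR,speed,4,random
MCAR,speed,5,zero
MCAR,speed,6,mean
MCAR,speed,7,knn
MCAR,speed,8,svd
MCAR,speed,9,qrilc
MCAR,speed,10,iterative_pca
MCAR,speed,11,forest
MAR,accuracy,1,iterative_pca
MAR,accuracy,2,svd
MAR,accuracy,3,forest
MAR,accuracy,4,knn
MAR,accuracy,5,median
MAR,accuracy,6,mean
MAR,accuracy,7,min
MAR,accuracy,8,qrilc
MAR,accuracy,9,half_min
MAR,accuracy,10,zero
MAR,accuracy,11,random
MAR,speed,1,min
MAR,speed,2,half_min
MAR,speed,3,median
MAR,speed,4,random
MAR,speed,5,zero
MAR,speed,6,mean
MAR,speed,7,knn
MAR,speed,8,svd
MAR,speed,9,qrilc
MAR,speed,10,iterative_pca
MAR,speed,11,forest
MNAR_LOD,accuracy,1,min
MNAR_LOD,accuracy,2,qrilc
MNAR_LOD,accuracy,3,half_min
MNAR_LOD,accuracy,4,iterative_pca
MNAR_LOD,accuracy,5,forest
MNAR_LOD,accuracy,6,svd
MNAR_LOD,accuracy,7,zero
MNAR_LOD,accuracy,8,knn
MNAR_LOD,accuracy,9,median
MNAR_LOD,accuracy,10,mean
MNAR_LOD,accuracy,11,random
MNAR_LOD,speed,1,min
MNAR_LOD,speed,2,half_min
MNAR_LOD,speed,3,median
MNAR_LOD,speed,4,random
MNAR_LOD,speed,5,zero
MNAR_LOD,speed,6,mean
MNAR_LOD,speed,7,knn
MNAR_LOD,speed,8,svd
MNAR_LOD,speed,9,qrilc
MNAR_LOD,speed,10,iterative_pca
MNAR_LOD,speed,11,forest
overall,accuracy,1,iterative_pca
overall,accuracy,2,svd
overall,accuracy,3,forest
overall,accuracy,4,knn
overall,accuracy,5,median
overall,accuracy,6,min
overall,accuracy,7,mean
overall,accuracy,8,qrilc
overall,accuracy,9,half_min
overall,accuracy,10,zero
overall,accuracy,11,random
overall,speed,1,min
overall,speed,2,half_min
overall,speed,3,median
overall,speed,4,random
overall,speed,5,zero
overall,speed,6,mean
overall,speed,7,knn
overall,speed,8,svd
overall,speed,9,qrilc
overall,speed,10,iterative_pca
overall,speed,11,forest
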