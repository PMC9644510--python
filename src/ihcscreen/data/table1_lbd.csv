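protein,level_normal,level_cancer,p_expression,expression_sig,compartment,p_location,location_sig
BCAR1,medium,low,0.5437,0,Nucl.,0.0455,1
ELAVL1,medium,high,0.7435,0,Cytopl.,3.6e-5,1
NDRG1,high,medium,3.37e-4,1,PlasMem.,0.1675,0
NDRG1,high,medium,3.37e-4,1,Nucl.,0.1005,0
CCNEL,medium,low,0.0706,0,Nucl.,0.8563,0
AHR,medium,low,0.0094,1,Nucl.,0.0158,1
p68,medium,low,0.0029,1,Cytopl.,4.6e-7,1
EBP50,high,medium,0.1086,0,Nucl.,0.0076,1
CDKN1B,medium,low,2.14e-3,1,Cytopl.,6.65e-8,1
CACYBP,medium,high,2.85e-7,1,Nucl.,1.03e-5,1
ARRB1,high,low,0.5986,0,PlasMem.,1.12e-3,1
p53,high,medium,9.34e-3,1,Cytopl.,0.0498,1
p53,high,medium,9.34e-3,1,Nucl.,0.0365,1
BRD4,high,low,0.0376,1,Nucl.,1.3e-5,1
AKT1,medium,low,1.04e-3,1,Cytopl.,0.0204,1
PRKCA,medium,low,2.13e-3,1,PlasMem.,4.04e-11,1
SMAD3,medium,low,0.0225,1,Nucl.,0.0249,1
HNRNPK,high,low,0.1058,0,Cytopl.,3.46e-4,1
HNRNPK,high,low,0.1058,0,Nucl.,0.0110,1
PRKCB,low,high,0.3276,0,PlasMem.,0.0240,1
beta-catenin,medium,low,0.6826,0,Cytopl.,1.65e-4,1
beta-catenin,medium,low,0.6826,0,Nucl.,2.86e-4,1
STAT3,medium,low,5.88e-4,1,Nucl.,5.2e-5,1
TET2,medium,high,0.0491,1,Cytopl.,1.86e-3,1
BCL2,low,medium,0.0203,1,Nucl.,0.2644,0
BCL2,low,medium,0.0203,1,PlasMem.,0.1820,0
CYSLT1,low,medium,0.0178,1,Nucl.,0.5582,0
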