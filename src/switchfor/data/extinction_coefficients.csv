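# Published Beer's-law light-extinction coefficients (k) for switchgrass
# canopies compiled from multi-site field trials and model parameterisations.
# Negative signs are a reporting convention in some sources; the model uses
# absolute values.
source,location,cultivar,k
Kiniry 1999,Texas US,Alamo,0.33
Kiniry 1999,Texas US,Alamo,0.33
Madakadze 1998,Quebec Canada,CIR,-0.54
Madakadze 1998,Quebec Canada,Pathfinder,-0.54
Madakadze 1998,Quebec Canada,Sunburst,-0.49
Kiniry 1996,Tennessee US,Alamo,0.65
Kiniry 2011,Nebraska US,Alamo,-0.31
Kiniry 2011,Nebraska US,Kanlow,-0.23
Kiniry 2011,Nebraska US,CIR,-0.36
Kiniry 2011,Nebraska US,Summer,-0.27
Kiniry 2011,Nebraska US,Shawnee,-0.29
Kiniry 2011,Nebraska US,Kanlow x Summer,-0.28
Kiniry 2011,Elsberry US,Alamo,-0.38
Kiniry 2011,Elsberry US,Kanlow,-0.67
Kiniry 2011,Elsberry US,CIR,-1.11
Kiniry 2011,Temple US,Alamo,0.34
Kiniry 2011,Temple US,Alamo,0.47
Kiniry 2011,Temple US,Alamo,0.43
Kiniry 2011,Temple US,Alamo,0.35
Kiniry 2011,Temple US,Alamo,0.34
Kiniry 2011,Temple US,Alamo,0.34
Kiniry 2011,Temple US,Alamo,0.39
Kiniry 2011,Temple US,Alamo,0.37
Kiniry 2011,Temple US,Alamo,0.44
Kiniry 2011,Temple US,Alamo,0.41
Kiniry 2011,Temple US,Alamo,0.35
Kiniry 2011,Temple US,Alamo,0.27
Kiniry 2011,Temple US,Alamo,0.36
Kiniry 2011,Temple US,Alamo,0.33
Trybula 2015,Purdue US,Shawnee,0.5
Behrman 2013,ALMANAC,Alamo,0.33
Behrman 2013,ALMANAC,Blackwell,0.33
Behrman 2013,ALMANAC,CIR,0.36
Behrman 2013,ALMANAC,Kanlow,0.5
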