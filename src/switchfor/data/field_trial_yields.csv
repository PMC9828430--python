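# Multi-site switchgrass field-trial validation pairs: measured spring-harvest
# yield versus model-simulated yield (Mg DM ha-1), one row per site-year.
# Sites span China, the US, Canada, the UK, Germany and France; cultivar and
# ecotype (upland/lowland) as reported by the source trials.
site,country,latitude,longitude,cultivar,ecotype,harvest_year,measured,modelled
Dekalb,US,41.85,-88.85,CIR,upland,2006,7.7,4.9
Dekalb,US,41.85,-88.85,CIR,upland,2007,6.0,6.0
Dekalb,US,41.85,-88.85,CIR,upland,2008,10.0,5.9
Dekalb,US,41.85,-88.85,CIR,upland,2009,5.0,7.1
Dekalb,US,41.85,-88.85,CIR,upland,2010,4.0,3.7
Dekalb,US,41.85,-88.85,CIR,upland,2011,10.0,4.1
Fairfield,US,38.95,-88.96,CIR,upland,2006,10.0,13.9
Fairfield,US,38.95,-88.96,CIR,upland,2007,16.0,16.6
Fairfield,US,38.95,-88.96,CIR,upland,2008,16.0,14.2
Fairfield,US,38.95,-88.96,CIR,upland,2009,11.0,16.3
Orr,US,39.81,-90.82,CIR,upland,2006,8.0,7.0
Orr,US,39.81,-90.82,CIR,upland,2007,15.0,9.1
Orr,US,39.81,-90.82,CIR,upland,2008,12.0,13.3
Orr,US,39.81,-90.82,CIR,upland,2009,9.0,13.4
Orr,US,39.81,-90.82,CIR,upland,2010,8.0,10.4
Orr,US,39.81,-90.82,CIR,upland,2011,10.0,10.7
South Farms,US,40.05,-88.20,CIR,upland,2006,14.7,14.8
South Farms,US,40.05,-88.20,CIR,upland,2007,13.2,12.9
South Farms,US,40.05,-88.20,CIR,upland,2008,10.5,11.4
McGill University,Canada,45.47,-73.75,Multi,upland,1993,8.8,9.0
McGill University,Canada,45.47,-73.75,Multi,upland,1994,10.2,14.0
McGill University,Canada,45.47,-73.75,Multi,upland,1995,11.8,11.4
McGill University,Canada,45.47,-73.75,Multi,upland,1996,11.1,12.1
Red River,US,46.95,-97.02,Sunburst,upland,1990,7.3,3.9
Red River,US,46.95,-97.02,Sunburst,upland,1991,9.3,13.9
Red River,US,46.95,-97.02,Sunburst,upland,1992,10.3,16.7
Guyuan,China,36.01,106.27,Multi,upland,2007,2.6,2.3
Guyuan,China,36.01,106.27,Multi,upland,2009,6.1,2.3
Guyuan,China,36.01,106.27,Multi,upland,2010,8.0,3.6
Yangling,China,34.20,108.11,Multi,upland,2009,12.6,9.1
Yangling,China,34.20,108.11,Multi,upland,2010,30.2,8.9
Dingbian,China,36.82,107.25,Multi,upland,2009,1.0,0.7
Dingbian,China,36.82,107.25,Multi,upland,2010,5.0,0.4
Dingbian,China,36.82,107.25,"Alamo, Kanlow",lowland,2010,1.4,1.3
Ansai,China,36.86,109.32,Alamo,lowland,2009,1.9,1.9
Ansai,China,36.86,109.32,Alamo,lowland,2010,2.8,3.2
Ansai,China,36.86,109.32,Alamo,lowland,2011,4.8,4.8
Ansai,China,36.86,109.32,Alamo,lowland,2012,7.8,7.0
Ansai,China,36.86,109.32,Alamo,lowland,2013,7.1,3.1
Ansai,China,36.86,109.32,Alamo,lowland,2014,6.8,7.2
Ansai,China,36.86,109.32,Alamo,lowland,2015,4.5,2.2
Ansai,China,36.86,109.32,Alamo,lowland,2016,4.9,4.3
Rothamsted Experimental Station Farm,UK,51.80,-0.35,Kanlow,lowland,1995,5.5,4.3
Rothamsted Experimental Station Farm,UK,51.80,-0.35,Kanlow,lowland,1996,6.2,8.4
Rothamsted Experimental Station Farm,UK,51.80,-0.35,Kanlow,lowland,1997,11.6,8.1
Rothamsted Experimental Station Farm,UK,51.80,-0.35,Kanlow,lowland,1998,14.0,13.7
Stephenville,US,32.22,-98.20,Alamo,lowland,1992,8.8,15.2
Stephenville,US,32.22,-98.20,Alamo,lowland,1993,12.3,13.7
Stephenville,US,32.22,-98.20,Alamo,lowland,1994,10.2,13.2
Stephenville,US,32.22,-98.20,Alamo,lowland,1995,16.1,18.1
Stephenville,US,32.22,-98.20,Alamo,lowland,1996,11.6,11.3
Stephenville,US,32.22,-98.20,Alamo,lowland,1997,12.4,12.1
Stephenville,US,32.22,-98.20,Alamo,lowland,1998,7.4,6.9
University of Hohenheim,Germany,48.73,8.93,Kanlow,lowland,2003,8.0,14.4
University of Hohenheim,Germany,48.73,8.93,Kanlow,lowland,2004,12.0,14.0
University of Hohenheim,Germany,48.73,8.93,Kanlow,lowland,2005,14.0,12.4
INRA experimental station,France,49.87,3.01,Kanlow,lowland,2007,19.6,14.0
INRA experimental station,France,49.87,3.01,Kanlow,lowland,2008,18.1,13.5
INRA experimental station,France,49.87,3.01,Kanlow,lowland,2009,17.6,16.9
INRA experimental station,France,49.87,3.01,Kanlow,lowland,2010,14.7,10.9
INRA experimental station,France,49.87,3.01,Kanlow,lowland,2011,14.3,13.4
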