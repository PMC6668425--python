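species,delta13c_diet,diet_sd,delta13c_ch4,ch4_sd,year,provenance,source_id
goat,-30.311,0.5,-73.065,4.0,1999,direct,4
steer,-30.263,0.5,-73.436,4.0,2008,direct,4
dairy cow,-29.565,0.5,-72.729,4.0,1995,composition,5
sheep,-29.536,0.5,-69.244,4.0,2003,direct,1
steer,-29.452,0.5,-74.487,4.0,2001,direct,2
dairy cow,-28.894,0.5,-64.582,4.0,2001,composition,4
sheep,-28.824,0.5,-67.558,4.0,2010,direct,6
sheep,-28.492,0.5,-66.207,4.0,2007,direct,2
cattle,-28.416,0.5,-69.909,4.0,1996,direct,2
cattle,-28.395,0.5,-74.32,4.0,2008,composition,1
cattle,-28.11,0.5,-70.007,4.0,2008,direct,1
sheep,-27.532,0.5,-71.809,4.0,2000,direct,2
cattle,-27.532,0.5,-65.011,4.0,1998,composition,6
cattle,-26.894,0.5,-69.701,4.0,2011,direct,5
cattle,-26.689,0.5,-64.989,4.0,2002,composition,5
goat,-26.133,0.5,-68.42,4.0,1995,direct,3
goat,-25.776,0.5,-63.721,4.0,2003,direct,2
dairy cow,-25.218,0.5,-63.081,4.0,2005,direct,1
steer,-24.831,0.5,-70.709,4.0,1997,direct,5
cattle,-24.439,0.5,-62.503,4.0,2008,composition,3
cattle,-22.602,0.5,-64.016,4.0,2002,direct,6
dairy cow,-21.894,0.5,-65.377,4.0,1998,composition,1
cattle,-21.518,0.5,-58.626,4.0,2012,direct,3
dairy cow,-21.17,0.5,-62.988,4.0,2002,direct,1
goat,-21.066,0.5,-63.181,4.0,1994,direct,3
dairy cow,-20.973,0.5,-63.884,4.0,2012,composition,1
goat,-20.653,0.5,-54.048,4.0,2000,composition,2
cattle,-20.427,0.5,-54.119,4.0,1997,composition,5
dairy cow,-20.303,0.5,-61.009,4.0,2000,composition,5
dairy cow,-20.103,0.5,-63.546,4.0,1997,direct,1
goat,-20.07,0.5,-70.697,4.0,2001,direct,4
sheep,-18.717,0.5,-64.479,4.0,2009,direct,6
cattle,-18.268,0.5,-70.385,4.0,2004,direct,5
sheep,-16.783,0.5,-57.435,4.0,2005,direct,1
steer,-16.763,0.5,-51.624,4.0,1999,composition,1
cattle,-15.842,0.5,-51.774,4.0,1997,direct,6
cattle,-15.382,0.5,-59.073,4.0,1995,composition,6
cattle,-14.5,0.5,-55.867,4.0,1994,composition,6
steer,-14.364,0.5,-53.363,4.0,1998,direct,1
goat,-14.343,0.5,-53.814,4.0,2007,direct,2
steer,-14.093,0.5,-54.972,4.0,1998,composition,4
cattle,-13.67,0.5,-63.176,4.0,1999,composition,6
goat,-13.221,0.5,-61.673,4.0,2004,direct,3
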