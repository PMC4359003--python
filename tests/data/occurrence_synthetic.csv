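lon,lat,status,source,period
11.2,56.1,infested,synthetic_panels_west,2006-2012
11.8,55.4,infested,synthetic_panels_west,2006-2012
12.4,56.8,infested,synthetic_panels_west,2006-2012
13.1,55.1,infested,synthetic_groynes,1993-1996
13.6,56.3,infested,synthetic_groynes,1993-1996
15.2,55.3,non_infested,synthetic_panels_island,2006-2012
16.8,56.9,non_infested,synthetic_panels_east,2006-2012
18.4,57.6,non_infested,synthetic_panels_east,2006-2012
19.9,58.2,non_infested,synthetic_panels_east,2006-2012
21.1,58.8,non_infested,synthetic_panels_east,2006-2012
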