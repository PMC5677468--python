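cache_id,study_area,elevation_zone,microsite,x,y,n_seeds_cached,located_y1,n_missing_y1,n_seed_coats_y1,n_germinants_y1,relocated_y2,n_live_seedlings_y2,n_new_germinants_y2
c01,site_a,treeline,rock,10.0,20.0,3,true,0,0,2,true,1,0
c02,site_a,treeline,no object,30.5,40.0,4,true,4,2,0,false,,
c03,site_a,treeline,tree,55.0,60.0,2,true,1,1,1,true,0,0
c04,site_a,subalpine,rock,15.0,80.0,5,true,2,0,1,true,1,1
c05,site_a,subalpine,open,70.0,25.0,3,true,0,0,0,true,0,1
c06,site_a,subalpine,tree,42.0,90.0,1,true,1,0,0,false,,
c07,site_b,treeline,rock,12.5,33.0,4,true,0,0,3,true,2,0
c08,site_b,treeline,open,88.0,14.0,3,true,1,1,2,true,0,0
c09,site_b,treeline,tree,64.0,71.0,3,true,0,0,0,true,0,2
c10,site_b,subalpine,rock,23.0,46.0,6,true,3,3,2,true,2,1
c11,site_b,subalpine,open,95.0,58.0,3,true,0,0,0,true,0,0
c12,site_b,subalpine,tree,37.0,62.0,3,false,,,,false,,
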