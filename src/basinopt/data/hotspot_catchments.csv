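id,region_id,downstream_id,src_manure,src_mineral,src_point,src_scattered,basin_retention,river_retention,discharge_Mm3
c01,r1,,2.096,1.156,0.729,0.447,0.3,0.1,71.1
c02,r1,c01,1.362,1.542,0.694,0.469,0.3,0.1,6.3
c03,r1,c02,1.398,1.164,0.553,0.502,0.3,0.1,5.4
c04,r1,c03,1.955,1.432,0.58,0.335,0.3,0.1,4.5
c05,r1,c04,1.859,0.886,0.718,0.432,0.3,0.1,3.6
c06,r1,c05,2.079,1.095,0.769,0.494,0.3,0.1,2.7
c07,r1,c06,2.101,0.98,0.588,0.291,0.3,0.1,1.8
c08,r1,c07,1.427,1.332,0.688,0.512,0.3,0.1,0.9
c09,r2,c01,18.134,12.451,6.627,3.662,0.2,0.05,4.8
c10,r2,c09,15.754,13.303,5.644,4.958,0.2,0.05,3.6
c11,r2,c10,19.486,16.195,7.561,3.993,0.2,0.05,2.4
c12,r2,c11,24.287,15.969,6.294,3.928,0.2,0.05,1.2
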