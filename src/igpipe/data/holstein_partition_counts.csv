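year_group,n_igp_male,n_igp_female,n_igp_total,n_gebv
2014-2018,144602,1304173,1448775,886176
2015-2018,117550,1171398,1288948,1046003
2016-2018,89025,1000120,1089145,1245806
2017-2018,57699,707181,764880,1570071
2018,23217,257044,280261,2054690
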