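country_id,headache_type,horizon_years,n_patients,additional_cost_provider,hlys_gained,icer_printed
Luxembourg,migraine,1,124713,2468610,1126,2192
Luxembourg,TTH,1,127501,-58977322,51,cost_saving
Luxembourg,MOH,1,14378,-304638,776,cost_saving
Luxembourg,migraine,5,124713,8148427,5265,1548
Luxembourg,TTH,5,127501,-59712128,239,cost_saving
Luxembourg,MOH,5,14378,-1423598,3625,cost_saving
Russia,migraine,1,18122512,215273678,163709,1315
Russia,TTH,1,26679239,-80743387,10695,cost_saving
Russia,MOH,1,7193081,-81939062,388112,cost_saving
Russia,migraine,5,18122512,1066657492,765026,1394
Russia,TTH,5,26679239,-153433010,49964,cost_saving
Russia,MOH,5,7193081,-382907727,1813677,cost_saving
Spain,migraine,1,10772263,216491177,97311,2225
Spain,TTH,1,7850265,-63402506,3146,cost_saving
Spain,MOH,1,2128185,-49026722,114829,cost_saving
Spain,migraine,5,10772263,688382902,454741,1514
Spain,TTH,5,7850265,-122434131,14702,cost_saving
Spain,MOH,5,2128185,-229105755,536604,cost_saving
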