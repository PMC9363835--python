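state,start_doy,end_doy,length_days,tmax_c,tmin_c,tav_c,gdd_c_day,mean_gsr_mm,optimum_gsr_mm,wl_mm,wl_pct,mean_wue,potential_wue,pct_below_optimum,yc,ya,yw,yga,ygw,yga_pct,ygw_pct
Illinois,91,309,218,23.9,12.0,18.0,2783,746,759,190,25,10,27,27,7.6,11.5,15.5,3.9,7.8,34,51
Indiana,94,311,217,23.8,11.9,17.9,2779,740,768,171,23,10,27,26,7.5,11.9,15.0,4.4,7.4,37,50
Iowa,100,306,206,24.1,11.9,18.0,2574,745,698,176,24,10,31,17,7.8,11.0,17.9,3.2,10.1,29,57
Kentucky,73,314,241,24.9,12.8,18.8,3278,936,880,214,23,8,27,21,6.7,9.2,19.4,2.5,12.8,28,66
Minnesota,113,282,169,22.8,10.7,16.8,1964,542,630,77,14,13,34,22,7.0,10.5,15.6,3.5,8.6,33,55
Missouri,82,316,234,24.8,12.6,18.7,3152,827,719,195,24,7,27,12,5.6,8.7,17.0,3.1,11.4,36,67
New York,109,298,189,22.5,10.6,16.6,2156,632,587,154,24,8,34,14,4.8,6.9,16.1,2.1,11.3,31,70
North Dakota,115,284,170,23.4,9.8,16.6,1935,366,391,75,21,12,27,13,4.8,7.4,7.8,2.6,3.0,35,39
Ohio,92,307,215,23.8,11.7,17.8,2692,693,645,215,31,11,38,22,7.2,10.1,18.2,2.9,11.1,29,61
Pennsylvania,94,306,212,23.6,11.5,17.6,2624,743,636,253,34,8,31,19,5.9,8.5,15.4,2.7,9.5,31,62
South Dakota,109,294,185,24.2,10.7,17.5,2268,441,688,109,25,13,34,47,5.8,10.9,11.2,5.1,5.4,47,48
Wisconsin,107,300,193,22.1,10.5,16.3,2155,648,635,126,19,10,27,15,5.8,9.1,14.1,3.3,8.3,36,59
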