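label,arm,category,timing,basis,quantity_6mo,quantity_12mo,rate_ref,unit_price,life_years,use_years,scaling_role,in_cumulative_total
Training,intervention,personnel_training,one_time,amount,471,471,,,,,fixed,1
Intervention delivery,intervention,personnel_delivery,per_phase,amount,5674,8083,,,,,variable,1
Website maintenance,intervention,website_maintenance,per_phase,amount,270,490,,,,,variable,1
Website hosting,intervention,website_hosting,recurring_monthly,unit,6,12,,75,,,fixed,1
Technical support,intervention,website_technical_support,recurring_monthly,unit,12,24,,95,,,fixed,1
Computer,intervention,hardware,one_time,purchase,1,1,,700,5,3,fixed,1
Printer,intervention,hardware,one_time,purchase,1,1,,400,5,3,fixed,1
Pedometers,intervention,materials,one_time,unit,104,104,,12.50,,,variable,1
"Paper, ink, binders",intervention,materials,one_time,amount,597,597,,,,,variable,1
Videos,intervention,materials,one_time,unit,15,15,,10,,,variable,0
Training,control,personnel_training,one_time,amount,157,157,,,,,fixed,1
Intervention delivery,control,personnel_delivery,per_phase,amount,1976,3119,,,,,variable,1
Website maintenance,control,website_maintenance,per_phase,amount,8,10,,,,,variable,1
Website hosting,control,website_hosting,recurring_monthly,unit,6,12,,75,,,fixed,1
Technical support,control,website_technical_support,recurring_monthly,unit,12,24,,95,,,fixed,1
Computer,control,hardware,one_time,purchase,1,1,,700,5,3,fixed,1
Printer,control,hardware,one_time,purchase,1,1,,400,5,3,fixed,1
"Paper, ink, binders",control,materials,one_time,amount,510,510,,,,,variable,1
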