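# NHS/PSS unit costs, 2018-19 price year (toy values shaped like the
# PSSRU / National Cost Collection sources)
item,unit,unit_cost,source,price_year
gp_visit,consultation,39.0,PSSRU-style,2018-19
nurse_visit,consultation,11.0,PSSRU-style,2018-19
outpatient,attendance,135.0,NCC-style,2018-19
emergency,attendance,160.0,NCC-style,2018-19
overnight_stay,night,345.0,NCC-style,2018-19
social_care,contact,25.0,PSSRU-style,2018-19
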