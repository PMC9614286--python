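drug_name,atc_code,dose_mg_low,dose_mg_high,duration_months,drug_class
buserelin,L02AE0,0,2,0.0328515,lhrh_analogue
buserelin,L02AE0,3.30,3.30,1,lhrh_analogue
buserelin,L02AE0,6.60,6.60,2,lhrh_analogue
buserelin,L02AE0,9.90,9.90,3,lhrh_analogue
goserelin,L02AE03,10.80,10.80,3,lhrh_analogue
histrelin,H01CA0,3.60,3.60,1,lhrh_analogue
histrelin,H01CA0,50,50,12,lhrh_analogue
leuprorelin,L02AE02,0,2,0.0328515,lhrh_analogue
leuprorelin,L02AE02,3.75,3.75,1,lhrh_analogue
leuprorelin,L02AE02,7.50,7.50,2,lhrh_analogue
leuprorelin,L02AE02,11.25,11.25,3,lhrh_analogue
leuprorelin,L02AE02,22.5,22.5,6,lhrh_analogue
leuprorelin,L02AE02,30,30,6,lhrh_analogue
leuprorelin,L02AE02,45,45,6,lhrh_analogue
nafarelin,H01CA02,0,2,0.0328515,lhrh_analogue
triptorelin,L02AE04,0,2,0.0328515,lhrh_analogue
triptorelin,L02AE04,3.75,3.75,1,lhrh_analogue
triptorelin,L02AE04,11.25,11.25,3,lhrh_analogue
triptorelin,L02AE04,22.5,22.5,6,lhrh_analogue
bicalutamide,L02BB03,50,50,1,antiandrogen
flutamide,L02BB0,250,250,1,antiandrogen
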