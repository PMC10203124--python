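grid_id,supplier_name,parameter_of_interest,film_material,hole_diameter_um,hole_spacing_um,mesh,square_size_um,bar_metal,measured_pmax_W_cm2,censor
cf21_200cu,CF 2/1 2Cu,mesh,carbon_cflat,2,1,200,90,copper,43,none
cf312_300cu,CF312 (2/1 3Cu),mesh,carbon_cflat,2,1,300,58,copper,64,none
cf412_400cu,CF412 (2/1 4Cu),mesh,carbon_cflat,2,1,400,37,copper,96,none
cf200cu_ul,CF200-Cu-UL,film_material,carbon_cflat,,,200,90,copper,50,lt
ff200cu,FF200-Cu,film_material,formvar,,,200,90,copper,690,gt
sf200cu,SF200-Cu,film_material,silicon_monoxide,,,200,90,copper,690,gt
sf200ni,SF200-Ni,film_material,silicon_monoxide,,,200,90,nickel,690,gt
ultraufoil_1213_300au,UltrAuFoil (1.2/1.3 3Au),film_material,gold_film,1.2,1.3,300,58,gold,254,none
cf313_300cu,CF313 (1.2/1.3 3Cu),bar_metal,carbon_cflat,1.2,1.3,300,58,copper,50,none
cf1213_300au,CF 1.2/1.3 3Au,bar_metal,carbon_cflat,1.2,1.3,300,58,gold,50,none
cf312_300cu,CF312 (2/1 3Cu),film_geometry,carbon_cflat,2,1,300,58,copper,64,none
cf313_300cu,CF313 (1.2/1.3 3Cu),film_geometry,carbon_cflat,1.2,1.3,300,58,copper,50,none
qf21_200cu,QF 2/1 2Cu,film_geometry,carbon_quantifoil,2,1,200,90,copper,23,none
qf14_200au,QF 1/4 2Au,film_geometry,carbon_quantifoil,1,4,200,90,gold,16,none
cf21_200cu,CF 2/1 2Cu,manufacturing,carbon_cflat,2,1,200,90,copper,43,none
qf21_200cu,QF 2/1 2Cu,manufacturing,carbon_quantifoil,2,1,200,90,copper,23,none
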