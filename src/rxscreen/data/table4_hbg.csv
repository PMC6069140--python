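api_name,variant,wsv_ug_L,hbg_ug_L,protection_ratio,ltd_mg_kg_d,af_c,af_e,uf_human,uf_l_n,uf_db,uf_s_c,total_uf,rsc,inconsistent_as_printed
Acetaminophen,one_tablet_per_day,9,200,22,3.75,1,1,10,10,3,10,3000,0.2,true
Acetaminophen,six_tablets_per_day,50,200,4,22.5,1,1,10,10,3,10,3000,0.2,true
Carbamazepine,,0.9,40,44,1,10,1,10,10,1,3,3000,0.8,false
17a-Ethinylestradiol,,0.0001,0.0002,2,0.00044,1,10,10,10,3,3,3000,0.8,true
Sulfamethoxazole,,0.4,100,250,4.57,1,10,10,10,3,10,30000,0.8,false
Venlafaxine,,0.3,10,33,25,1,1,10,10,3,10,3000,0.8,true
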