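group,stage,n_embryos,asv_mean,asv_sd,vsv_mean,vsv_sd,ratio_mean,ratio_sd,la_edv_mean,la_edv_sd,ra_edv_mean,ra_edv_sd,lv_edv_mean,lv_edv_sd,rv_edv_mean,rv_edv_sd,cycle_period,n_frames,apex_sharpness,av_junction_medial_offset,la_narrowing_factor,oft_diameter,atrial_duty
control,HH25,5,0.528,0.274,0.644,0.321,0.87,0.36,0.48,0.145,0.48,0.145,0.4954,0.17,0.4954,0.17,0.45,40,2.5,0.0,1.0,0.28,0.25
LAL,HH25,4,0.303,0.082,0.764,0.138,0.42,0.16,0.1296,0.008,0.50,0.08,0.55,0.079,0.6254,0.079,0.45,40,6.0,0.12,0.27,0.36,0.15
control,HH28,4,1.12,0.35,1.381,0.40,0.82,0.25,0.96,0.15,0.96,0.15,1.179052,0.30,0.946214,0.25,0.42,40,2.5,0.0,1.0,0.36,0.25
LAL,HH28,4,0.65,0.18,1.55,0.35,0.44,0.15,0.16,0.02,1.10,0.20,0.6270,0.10,1.757374,0.30,0.42,40,5.0,0.10,0.30,0.38,0.18
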