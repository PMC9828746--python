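# Almond-orchard tunnel residue study, summary-level fixture: one row per
# matrix holds the study peak (with its day) and one row the study minimum;
# fully censored matrices carry "<MDL" rows.  Matrix-specific LOQ/MDL in
# mg/kg.  whole_bees for trisiloxane-acetoxy is invalid (frozen-storage
# instability).  control=1 rows are untreated-plot samples (all censored).
chemical,matrix,day,replicate,conc,loq,mdl,control,invalid
trisiloxane-317,forager_pollen,1,1,76.2,0.400,0.0713,0,0
trisiloxane-317,forager_pollen,10,1,6.77,0.400,0.0713,0,0
trisiloxane-317,bee_bread,7,1,40.5,0.400,0.0954,0,0
trisiloxane-317,bee_bread,0,1,<0.0954,0.400,0.0954,0,0
trisiloxane-317,forager_nectar,10,1,2.12,0.400,0.0634,0,0
trisiloxane-317,forager_nectar,0,1,<0.0634,0.400,0.0634,0,0
trisiloxane-317,stored_nectar,7,1,0.177,0.400,0.0634,0,0
trisiloxane-317,stored_nectar,0,1,<0.0634,0.400,0.0634,0,0
trisiloxane-317,larvae,7,1,0.768,0.400,0.0666,0,0
trisiloxane-317,larvae,0,1,<0.0666,0.400,0.0666,0,0
trisiloxane-317,wax,7,1,12.1,0.320,0.0688,0,0
trisiloxane-317,wax,0,1,<0.0688,0.320,0.0688,0,0
trisiloxane-317,whole_bees,7,1,8.32,0.400,0.0509,0,0
trisiloxane-317,whole_bees,0,1,<0.0509,0.400,0.0509,0,0
trisiloxane-317,forager_pollen,0,1,<0.0713,0.400,0.0713,1,0
trisiloxane-317,forager_nectar,0,1,<0.0634,0.400,0.0634,1,0
trisiloxane-OH,forager_pollen,0,1,26.5,0.100,0.0152,0,0
trisiloxane-OH,forager_pollen,10,1,0.163,0.100,0.0152,0,0
trisiloxane-OH,bee_bread,1,1,17.3,0.100,0.0100,0,0
trisiloxane-OH,bee_bread,0,1,2.99,0.100,0.0100,0,0
trisiloxane-OH,forager_nectar,7,1,0.48,0.100,0.0143,0,0
trisiloxane-OH,forager_nectar,0,1,0.0213,0.100,0.0143,0,0
trisiloxane-OH,stored_nectar,10,1,0.0662,0.100,0.0143,0,0
trisiloxane-OH,stored_nectar,0,1,<0.0143,0.100,0.0143,0,0
trisiloxane-OH,larvae,10,1,0.147,0.100,0.0207,0,0
trisiloxane-OH,larvae,0,1,<0.0207,0.100,0.0207,0,0
trisiloxane-OH,wax,7,1,1.22,0.100,0.0148,0,0
trisiloxane-OH,wax,0,1,<0.0148,0.100,0.0148,0,0
trisiloxane-OH,whole_bees,7,1,2.45,0.100,0.0168,0,0
trisiloxane-OH,whole_bees,0,1,<0.0168,0.100,0.0168,0,0
trisiloxane-OH,forager_pollen,0,1,<0.0152,0.100,0.0152,1,0
trisiloxane-acetoxy,forager_pollen,0,1,4.53,0.100,0.0151,0,0
trisiloxane-acetoxy,forager_pollen,10,1,0.112,0.100,0.0151,0,0
trisiloxane-acetoxy,bee_bread,1,1,2.65,0.100,0.0072,0,0
trisiloxane-acetoxy,bee_bread,0,1,0.545,0.100,0.0072,0,0
trisiloxane-acetoxy,forager_nectar,0,1,<0.0119,0.100,0.0119,0,0
trisiloxane-acetoxy,forager_nectar,7,1,<0.0119,0.100,0.0119,0,0
trisiloxane-acetoxy,stored_nectar,0,1,<0.0119,0.100,0.0119,0,0
trisiloxane-acetoxy,stored_nectar,7,1,<0.0119,0.100,0.0119,0,0
trisiloxane-acetoxy,larvae,0,1,<0.0138,0.100,0.0138,0,0
trisiloxane-acetoxy,larvae,7,1,<0.0138,0.100,0.0138,0,0
trisiloxane-acetoxy,wax,10,1,0.332,0.100,0.0109,0,0
trisiloxane-acetoxy,wax,0,1,<0.0109,0.100,0.0109,0,0
trisiloxane-acetoxy,whole_bees,0,1,<0.0131,0.100,0.0131,0,1
trisiloxane-acetoxy,whole_bees,7,1,<0.0131,0.100,0.0131,0,1
trisiloxane-acetoxy,forager_nectar,0,1,<0.0119,0.100,0.0119,1,0
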