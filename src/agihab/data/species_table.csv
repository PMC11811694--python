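species_id,name,common_name,min_depth_m,max_depth_m,suitability_threshold,source,t_pref_c,po2_thr_mbar,agi_crit,t_pref_c_p08,po2_thr_mbar_p08,agi_crit_p08
1,Dissostichus mawsoni,Antarctic toothfish,0,2210,,a,0.06,120.2,1.26,-0.18,120.4,1.35
2,Pagothenia borchgrevinki,Bald rockcod,0,30,,b,-1.53,160.5,1.40,-1.51,166.3,1.40
3,Chaenocephalus aceratus,Blackfin icefish,0,770,,c,0.22,118.7,1.25,0.82,121.5,1.24
4,Notothenia coriiceps,Black rockcod,0,550,,d,-0.73,127.1,1.22,-0.66,125.4,1.13
5,Pleuragramma antarctica,Antarctic silverfish,0,1000,,e,-0.77,125.2,1.34,-0.72,123.8,1.34
6,Euphausia superba,Antarctic krill,0,600,,f,1.80,117.7,1.34,0.88,116.1,1.32
7,Euphausia crystallorophias,Ice krill,0,650,,b,0.55,116.6,1.28,-0.78,121.7,1.32
8,Notothenia rossii,Marbled rockcod,5,350,,e,3.02,129.5,1.40,3.68,132.0,1.38
9,Trematomus hansoni,Striped rockcod,6,549,,e,-0.87,127.2,1.30,-0.82,124.8,1.24
10,Lepidonotothen squamifrons,Grey rockcod,10,900,,e,-0.26,122.8,1.17,0.55,122.3,1.20
11,Muraenolepis microps,Smalleye moray cod,10,1600,,e,-0.12,120.6,1.31,-0.21,122.6,1.29
12,Neopagetopsis ionah,Jonah's icefish,20,900,,e,-0.68,123.2,1.34,-0.70,124.4,1.34
13,Amblyraja georgiana,Antarctic starry skate,57,173,,b,1.88,141.6,1.48,-0.02,141.0,1.37
14,Trematomus loennbergii,Scaly rockcod,65,832,,b,-0.71,123.2,1.34,-0.85,125.8,1.33
15,Gymnodraco acuticeps,Ploughfish,66,247,,b,-1.06,139.0,1.33,-1.04,136.3,1.32
16,Chionodraco hamatus,Crocodile icefish,76,271,,b,-1.00,135.0,1.32,-0.99,129.2,1.31
17,Cryodraco antarcticus,Long-fingered icefish,90,600,,e,-0.81,126.3,1.33,-0.76,122.0,1.32
18,Bathyraja maccaini,McCain's skate,167,500,,d,3.07,120.9,1.35,0.02,117.3,1.33
19,Galiteuthis glacialis,Glass squid,200,2500,0.228,g,9.91,121.3,1.92,9.91,121.3,1.92
20,Chaenodraco wilsoni,Spiny icefish,200,800,,e,-0.53,121.3,1.35,-0.54,120.5,1.35
21,Mesonychoteuthis hamiltoni,Colossal squid,200,600,0.121,h,2.80,117.0,1.40,2.80,117.0,1.40
22,Antarctomysis maxima,Opossum shrimp,220,440,,b,-0.25,123.2,1.18,-0.39,122.8,1.19
23,Lycenchelys aratrirostris,Lycodine eelpout,244,376,,b,-0.76,119.9,1.31,-0.79,127.39,1.33
24,Trematomus lepidorhinus,Slender scalyhead,272,468,,b,-0.65,122.3,1.34,-0.90,129.0,1.33
25,Anotopterus vorax,Southern Ocean daggertooth,358,1059,,b,0.25,117.8,1.32,0.27,117.7,1.32
26,Psychroteuthis glacialis,Glacial squid,385,610,,b,0.03,119.7,1.19,-0.08,118.3,1.22
27,Macrourus whitsoni,Whitson's grenadier,400,3185,,e,0.06,122.1,1.24,-0.15,121.7,1.33
28,Kondakovia longimana,Oceanic squid,500,2000,0.281,i,0.64,121.5,1.27,0.64,121.5,1.27
29,Chionobathyscus dewitti,Crocodile icefish,500,2000,,e,-0.13,120.6,1.36,-0.25,125.2,1.37
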