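island,species,count,precision,method
Beagle,adeliae,284535,N2,uav
Brash,adeliae,94951,N2,uav
Comb,adeliae,12000,N4,photo
Darwin,adeliae,5804,N1,photo
Dixey Rock,adeliae,0,N1,ground
Earle,adeliae,21071,N2,uav
Heroina,adeliae,292363,N2,uav
Platter,adeliae,40803,N1,ground
Scud Rock,adeliae,0,N1,ground
Beagle,papua,0,N1,ground
Brash,papua,2270,N1,ground
Comb,papua,186,N1,ground
Darwin,papua,0,N1,ground
Dixey Rock,papua,0,N1,ground
Earle,papua,847,N1,ground
Heroina,papua,999,N1,ground
Platter,papua,223,N1,ground
Scud Rock,papua,0,N1,ground
Beagle,antarctica,0,N1,ground
Brash,antarctica,0,N1,ground
Comb,antarctica,0,N1,ground
Darwin,antarctica,0,N1,ground
Dixey Rock,antarctica,0,N1,ground
Earle,antarctica,0,N1,ground
Heroina,antarctica,27,N1,ground
Platter,antarctica,0,N1,ground
Scud Rock,antarctica,0,N1,ground
Beagle,atriceps,0,N1,ground
Brash,atriceps,156,N1,ground
Comb,atriceps,0,N1,ground
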