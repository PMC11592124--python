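species,valence,conc_out_mM,conc_in_mM,rel_permeability,chem_potential_kJ_mol,equil_potential_mV
Na+,1,18,150,0.04,-261.89,56
K+,1,140,5,1,-283.26,-89
Cl-,-1,120,7,0.45,-131.26,-76
Ca2+,2,1.2,0.1,0,-553.04,125
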