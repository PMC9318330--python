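name,ion_formula,charge,n_tracer_positions
Ala,C11H26NO2Si2,1,3
Ser,C17H40NO3Si3,1,3
Gly,C10H24NO2Si2,1,2
Asp,C18H40NO4Si3,1,4
Glu,C19H42NO4Si3,1,5
Pro,C13H28NO2Si2,1,5
3PG,C17H40O7PSi3,1,3
PEP,C11H24O6PSi2,1,3
Pyr,C6H12NO2Si,1,3
Lac,C11H25O3Si2,1,3
Cit,C26H55O7Si4,1,6
aKG,C14H28NO5Si2,1,5
Suc,C12H25O4Si2,1,4
Fum,C12H23O4Si2,1,4
Mal,C18H39O5Si3,1,4
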