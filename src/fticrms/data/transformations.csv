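# Common biochemical mass-difference transformations for molecular networking.
# delta_mass is recomputed from the formula at load time; the column here is
# informational (5 decimal places).
name,formula,delta_mass
H2,H2,2.01565
CH2,CH2,14.01565
CH4,CH4,16.03130
O,O,15.99491
NH,NH,15.01090
NH2,NH2,16.01872
NH3,NH3,17.02655
H2O,H2O,18.01056
C2H2,C2H2,26.01565
CO,CO,27.99491
CH2N,CH3N,29.02655
CH2O,CH2O,30.01057
C2H4,C2H4,28.03130
S,S,31.97207
H2S,H2S,33.98772
CH3OH,CH4O,32.02621
C3H6,C3H6,42.04695
C2H2O,C2H2O,42.01057
CO2,CO2,43.98983
CH2O2,CH2O2,46.00548
C4H8,C4H8,56.06260
glycine,C2H3NO,57.02146
C3H4O,C3H4O,56.02621
acetic_acid,C2H4O2,60.02113
alanine,C3H5NO,71.03711
C3H6O2,C3H6O2,74.03678
serine,C3H5NO2,87.03203
SO3,SO3,79.95682
HPO3,HPO3,79.96633
cysteine,C3H5NOS,103.00919
H3PO4,H3PO4,97.97690
malonyl,C3H2O3,86.00039
aspartate,C4H5NO3,115.02694
glutamine,C5H8N2O2,128.05858
glutamate,C5H7NO3,129.04259
pentose,C5H8O4,132.04226
deoxyhexose,C6H10O4,146.05791
hexose,C6H10O5,162.05282
glucuronyl,C6H8O6,176.03209
sulfoglucose,C6H10O8S,242.00965
phenylalanine,C9H9NO,147.06841
hydroxybenzoyl,C7H4O2,120.02113
coumaroyl,C9H6O2,146.03678
caffeoyl,C9H6O3,162.03169
feruloyl,C10H8O3,176.04734
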