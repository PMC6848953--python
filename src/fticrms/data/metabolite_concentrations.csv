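# Primary metabolites of Sphagnum fallax quantified by 1H NMR (literature
# transcription). Concentrations in uM per 50 mg sample in 1 ml DI H2O;
# detection limit ~1 uM; published values carry 3 significant figures.
# The published table prints fructose 2,480 while the accompanying text says
# 2,490; this transcription carries the table value.
name,kegg_id,formula,concentration_uM,compound_class
Dimethylamine,C00543,C2H7N,10.2,Amines
4-Aminobutyrate,C00334,C4H9NO2,142,Amines
Methylamine,C00218,CH5N,3.3,Amines
Propylene glycol,C00583,C3H8O2,2.2,Polyols
Glycerol,C00116,C3H8O3,254,Polyols
O-Phosphocholine,C00588,C5H15NO4P,3.8,Cholines
Choline,C00114,C5H14NO,43.0,Cholines
Quinone,C00472,C6H4O2,9.3,Quinones
Methanol,C00132,CH4O,7.6,Alcohol
Pyruvate,C00022,C3H4O3,6.0,Acids
Lactate,C00186,C3H6O3,12.0,Acids
3-Hydroxybutyrate,C01089,C4H8O3,12.1,Acids
Acetate,C00033,C2H4O2,236,Acids
Fumarate,C00122,C4H4O4,13.2,Acids
Malate,C00711,C4H6O5,555,Acids
Formate,C00058,CH2O2,175,Acids
Isoleucine,C00407,C6H13NO2,27.5,Amino Acids
Phenylalanine,C00079,C9H11NO2,30.7,Amino Acids
Uridine,C00299,C9H12N2O6,30.0,Amino Acids
Leucine,C00123,C6H13NO2,45.2,Amino Acids
Valine,C00183,C5H11NO2,58.4,Amino Acids
Alanine,C00041,C3H7NO2,160,Amino Acids
Threonine,C00188,C4H9NO3,41.6,Amino Acids
Asparagine,C00152,C4H8N2O3,188,Amino Acids
Aspartate,C00049,C4H7NO4,210,Amino Acids
Glucose,C00031,C6H12O6,796,Sugars
Fructose,C00095,C6H12O6,2480,Sugars
Sucrose,C00089,C12H22O11,26.5,Sugars
myo-Inositol,C00137,C6H12O6,48.9,Sugars
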