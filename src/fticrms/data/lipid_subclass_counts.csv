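# Lipid identifications of Sphagnum fallax by class and subclass
# (LC-MS/MS, positive and negative modes; literature transcription).
# The final row is the embedded total used as a consistency check.
category,subclass,count
Sphingolipid,Cer,20
Sphingolipid,HexCer,3
Sphingolipid,PE-Cer,3
Sphingolipid,MIPC,1
Prenyl lipid,CoQ,1
Glycerophospholipid,CL,1
Glycerophospholipid,PA,4
Glycerophospholipid,PC-lyso,3
Glycerophospholipid,PC,12
Glycerophospholipid,PE,25
Glycerophospholipid,PG,7
Glycerophospholipid,PI,2
Glycerolipid,DGDG,4
Glycerolipid,DGTS/A,10
Glycerolipid,SQDG,1
Glycerolipid,DG,3
Glycerolipid,TG,18
Unknown,Unknown_NL299-256-244_PI267,28
Unknown,Unknown_NL299-256-244-60_PI267,6
,Total identifications,152
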