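# Known antimicrobial compounds confirmed by FTICR-MS in medicinal plants and
# shared with Sphagnum fallax (literature transcription; negative-mode study).
# notes: flags carried over from the published table footnotes.
name,formula,source,notes
O-glycoside-aglycones apigenin,C15H10O5,CBD,
O-glycoside-luteolin,C15H10O6,CBD,confirmed by LC-MS/MS; isomer of kaempferol
Tetrahydrocannabinolic acid,C22H30O4,CBD,
O-glycoside-kaempferol,C21H20O11,CBD,confirmed by LC-MS/MS; isomer of luteolin glucoside
Umbelliferone,C9H6O3,Chamomile,
Isorhamnetin,C16H12O7,Chamomile,
Luteolin glucoside,C21H20O11,Chamomile,isomer of O-glycoside-kaempferol
Quercetin glycoside,C21H20O12,Chamomile,
Coumaric acid,C9H8O3,Chia,
Quinic acid,C7H12O6,Chia,
Syringic acid-glucoside,C15H18O9,Chia,
Caffeoylquinic acid,C16H18O9,Chia,confirmed by LC-MS/MS
Methyl rosmarinic acid-glucoside,C18H16O8,Chia,
Dodecanoic acid,C12H24O2,Cinnamon,possible lipid isomer - fatty acid 12:0
Palmitic acid ethyl ester,C18H36O2,Creosote,
Veratric acid,C9H10O4,Mullein,
Kaempferol,C15H10O6,Senna,confirmed by LC-MS/MS; isomer of O-glycoside-luteolin
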