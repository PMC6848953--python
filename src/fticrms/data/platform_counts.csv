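# Metabolite detections per analytical platform (literature transcription).
platform,count
1H NMR,29
LC-MS/MS positive mode,234
LC-MS/MS negative mode,240
Lipidomics LC-MS/MS,152
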