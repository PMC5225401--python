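# PSI-MI experimental interaction detection method lexicon (methods under MI:0045).
# Format: MI id <TAB> canonical name|synonym|synonym...
# Covers the 35 methods observed in the annotated corpus; synonym lists are
# included where documented (MI:0004, MI:0018, MI:0809), otherwise canonical only.
MI:0004	affinity chromatography technology|affinity chrom|affinity purification
MI:0006	anti bait coimmunoprecipitation
MI:0007	anti tag coimmunoprecipitation
MI:0014	adenylate cyclase complementation
MI:0017	classical fluorescence spectroscopy
MI:0018	two hybrid|two-hybrid|yeast two hybrid|2 hybrid|2-hybrid|y2h|classical two hybrid|gal4 transcription regeneration|2h
MI:0019	coimmunoprecipitation
MI:0029	cosedimentation through density gradient
MI:0030	cross-linking study
MI:0040	electron microscopy
MI:0053	fluorescence polarization spectroscopy
MI:0054	fluorescence-activated cell sorting
MI:0055	fluorescent resonance energy transfer
MI:0065	isothermal titration calorimetry
MI:0071	molecular sieving
MI:0077	nuclear magnetic resonance
MI:0081	peptide array
MI:0096	pull down
MI:0104	static light scattering
MI:0107	surface plasmon resonance
MI:0114	x-ray crystallography
MI:0276	blue native page
MI:0402	chromatin immunoprecipitation assay
MI:0411	enzyme linked immunosorbent assay
MI:0412	electrophoretic mobility supershift assay
MI:0413	electrophoretic mobility shift assay
MI:0416	fluorescence microscopy
MI:0419	gtpase assay
MI:0423	in-gel kinase assay
MI:0426	light microscopy
MI:0663	confocal microscopy
MI:0676	tandem affinity purification
MI:0809	bimolecular fluorescence complementation|bifc
MI:0858	immunodepleted coimmunoprecipitation
MI:0889	acetylase assay
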