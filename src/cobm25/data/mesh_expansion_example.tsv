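# Example expansion lexicon (static MeSH-style synonyms), TSV: term <TAB> expansion
Liposarcoma	Myxoid
CDK4 Amplification	Cyclin-Dependent Kinase 4
CDK4 Amplification	Proto-Oncogene Proteins c-mdm2
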