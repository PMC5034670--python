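# UMLS semantic types counted as diseases or injuries (the DISO semantic
# group), used to filter annotation candidates. One type code per line.
T019
T020
T037
T046
T047
T048
T049
T050
T184
T190
T191
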