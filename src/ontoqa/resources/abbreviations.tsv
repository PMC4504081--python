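KO	knockout
ID	identifier
IDs	identifiers
5'	five prime
3'	three prime
T.cruzi	Trypanosoma cruzi
T.brucei	Trypanosoma brucei
L.major	Leishmania major
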