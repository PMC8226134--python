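species,Lysozyme,TPP,CIT,TRIS,Na+_TPP,Na+_CIT,Cl-
Lysozyme,3.8,,,5.7,,,0.9
TPP,,,,,51.1,,
CIT,,,,,,16.3,
TRIS,5.7,,,0.0,,,0.1
Na+,,51.1,16.3,,0.0,,
Cl-,0.9,,,0.1,,,
Water,918.5,76.0,91.3,54.1,79.9,69.8,137.8
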