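environment,TRIS,TPP,CIT
WP,906.9,843.1,837.2
WPP,5.2,15.0,15.4
WEP,6.4,7.8,11.0
WEPP,0.0,0.3,0.5
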