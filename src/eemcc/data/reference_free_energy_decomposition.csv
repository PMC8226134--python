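species,dG_TPP,dG_CIT,dH_TPP,dH_CIT,TdS_TPP,TdS_CIT
Lysozyme,-297,-226,-287,-267,10,-42
Polyanion,131,-76,136,-29,5,47
TRIS,-106,-85,-97,-80,9,6
Na+,4,-4,4,-4,1,0
Cl-,-3,-1,-3,-1,0,0
W_lysozyme,4,-14,28,17,23,32
W_polyanion,-43,31,-84,30,-41,-1
W_TRIS,34,40,38,43,4,3
W_Na+,2,-18,-28,-27,-29,-9
W_Cl-,-2,-1,0,1,2,2
Total,-276,-355,-293,-315,-17,39
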