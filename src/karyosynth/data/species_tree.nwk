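(GGA,(GHO,(LAG,(VSA,LRE,EQU,ACA)Toxicofera)Episquamata)Squamata)Amniota;
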