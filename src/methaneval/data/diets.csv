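diet_id,cp,ndf,nsc,ee,ash,ivdmd,leucaena,leucaena_species
toledo,6.5,69.2,11.4,2.51,10.5,64.1,false,
cayman,8.3,68.2,8.8,2.51,12.1,61.3,false,
star_kudzu,11.2,72.9,3.4,2.97,9.6,58.7,false,
cayman_ldiversifolia,14.7,56.8,12.5,3.46,12.5,60.4,true,L. diversifolia
cayman_lleucocephala,11.0,62.5,10.9,3.78,11.9,61.6,true,L. leucocephala
toledo_canavalia_ldiversifolia,10.8,66.5,10.2,2.92,9.6,61.2,true,L. diversifolia
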