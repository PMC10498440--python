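# Repeating units of well-known synthesized polymers, written with two
# wildcard attachment atoms.  Used as the default reference set for
# coverage/novelty evaluation of a generated library.
*CC*	polyethylene
*CC(C)*	polypropylene
*CC(*)c1ccccc1	polystyrene
*CC(*)Cl	poly(vinyl chloride)
*CC(*)O	poly(vinyl alcohol)
*CC(*)C#N	polyacrylonitrile
*CC(*)C(=O)OC	poly(methyl acrylate)
*CC=CC*	1,4-polybutadiene
*C(F)(F)C(F)(F)*	polytetrafluoroethylene
*CCO*	poly(ethylene oxide)
*CO*	polyoxymethylene
*CC(C)O*	poly(propylene oxide)
*Oc1c(C)cc(*)cc1C	poly(2,6-dimethylphenylene oxide)
*Oc1ccc(S(=O)(=O)c2ccc(*)cc2)cc1	polyethersulfone
*OC(C)C(*)=O	poly(lactic acid)
*OCC(*)=O	polyglycolide
*OCCCCCC(*)=O	polycaprolactone
*OCCOC(=O)c1ccc(C(*)=O)cc1	poly(ethylene terephthalate)
*OC(=O)Oc1ccc(C(C)(C)c2ccc(O*)cc2)cc1	bisphenol-A polycarbonate
*NCCCCCC(*)=O	nylon-6
*NCCCCCCNC(=O)CCCCC(*)=O	nylon-6,6
*Nc1ccc(NC(=O)c2ccc(C(*)=O)cc2)cc1	poly(p-phenylene terephthalamide)
*OCCOC(=O)NCCCCCCNC(*)=O	polyurethane (HDI / ethylene glycol)
*Sc1ccc(*)cc1	poly(phenylene sulfide)
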