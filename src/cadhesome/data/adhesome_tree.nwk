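((((((((((((((Hs:0.10,Mm:0.10)hsmm:0.10,Gg:0.20)amniota:0.05,Xt:0.25)tetrapoda:0.05,Dr:0.30)vertebrata_n:0.10,(Ci:0.30,Bf:0.30)invchordata:0.10)chordata:0.05,(Sp:0.40,(Dm:0.30,Ce:0.30)ecdysozoa:0.10)nonchordate:0.05)bilateria_n:0.05,(Hv:0.35,Nv:0.35)cnidaria_n:0.15)eumetazoa:0.05,Ta:0.55)parahoxozoa:0.05,(Aq:0.35,Oc:0.35)porifera_n:0.25)metazoa:0.10,(Mb:0.45,Sr:0.45)choanoflagellata_n:0.25)choanozoa:0.05,Co:0.75)filozoa:0.05,Sa:0.80)holozoa:0.10,((Am:0.45,(Mv:0.35,Spu:0.35)mucoromycota:0.10)chytrid_n:0.10,(Sc:0.45,Spo:0.45)dikarya:0.10)fungi_n:0.35)opisthokonta:0.10,(Dd:0.70,Tt:0.70)amoebozoa_n:0.30)root;
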