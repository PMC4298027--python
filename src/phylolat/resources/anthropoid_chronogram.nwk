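(((Hylobates_lar:20.0,(Gorilla_gorilla:10.0,(Pan_troglodytes:6.0,Homo_sapiens:6.0)HomoPan:4.0)Hominidae:10.0)Hominoidea:10.0,((Papio_anubis:11.5,(Miopithecus_talapoin:9.5,(Erythrocebus_patas:8.5,(Cercopithecus_mitis:6.5,Cercopithecus_ascanius:6.5)Cercopithecus:2.0)CercopithecinCore:1.0)Cercopithecini:2.0)Cercopithecinae:6.5,(Nasalis_larvatus:13.0,Procolobus_badius:13.0)Colobinae:5.0)Cercopithecoidea:12.0)Catarrhini:16.0,(Pithecia_monachus:25.0,((Alouatta_seniculus:19.0,(Ateles_geoffroyi:13.0,Lagothrix_lagotricha:13.0)Atelinae:6.0)Atelidae:4.0,Cebus_albifrons:23.0)CebidaeAtelidae:2.0)Platyrrhini:21.0)Anthropoidea;
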