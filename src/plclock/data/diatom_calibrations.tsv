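name	node_role	min_age	max_age	evidence	taxa
Diatoms stem node	stem		397	secondary	Anomoeoneis_sculpta;Cymbella_aspera;Cymbella_helvetica;Cymbella_mexicana;Cymbella_proxima;Cymbella_tumida;Cymbopleura_inaequalis;Cymbopleura_naviculiformis;Didymosphenia_dentata;Didymosphenia_siberica;Didymosphenia_geminata;Gomphoneis_minuta;Gomphonema_clevei;Mayamaea_atomus;Pinnularia_acuminata;Pinnularia_altiplanensis;Pinnularia_grunowii;Pinnularia_microstauron;Pinnularia_nodosa;Pinnularia_sp;Pinnularia_subcommutata;Pinnularia_viridiforme;Pinnularia_viridiformis;Sellaphora_blackfordensis;Cocconeis_stauroneiformis;Fragilaria_bidens;Pteroncola_inane;Nanofrustulum_shiloi;Opephora_sp;Pseudostaurosira_brevistriata;Licmophora_paradoxa;Tabularia_laevis;Diatoma_moniliforme;Thalassiothrix_longissima;Dimeregramma_minor;Rhaphoneis_sp;Plagiostriata_goreensis;Grammatophora_marina;Hyalosira_delicatula;Hyalosira_tropicalis;Rhabdonema_minutum;Cyclophora_tenuis;Pseudohimantidium_pacificum;Cymatosira_belgica;Odontella_sinensis;Cyclotella_meneghiniana;Stephanodiscus_sp;Skeletonema_tropicum;Thalassiosira_nordenskioeldii;Eunotogramma_laevis;Aulacoseira_granulata;Stephanopyxis_turris;Hyalodiscus_scoticus
Diatoms stem node	stem	190		fossil	Anomoeoneis_sculpta;Cymbella_aspera;Cymbella_helvetica;Cymbella_mexicana;Cymbella_proxima;Cymbella_tumida;Cymbopleura_inaequalis;Cymbopleura_naviculiformis;Didymosphenia_dentata;Didymosphenia_siberica;Didymosphenia_geminata;Gomphoneis_minuta;Gomphonema_clevei;Mayamaea_atomus;Pinnularia_acuminata;Pinnularia_altiplanensis;Pinnularia_grunowii;Pinnularia_microstauron;Pinnularia_nodosa;Pinnularia_sp;Pinnularia_subcommutata;Pinnularia_viridiforme;Pinnularia_viridiformis;Sellaphora_blackfordensis;Cocconeis_stauroneiformis;Fragilaria_bidens;Pteroncola_inane;Nanofrustulum_shiloi;Opephora_sp;Pseudostaurosira_brevistriata;Licmophora_paradoxa;Tabularia_laevis;Diatoma_moniliforme;Thalassiothrix_longissima;Dimeregramma_minor;Rhaphoneis_sp;Plagiostriata_goreensis;Grammatophora_marina;Hyalosira_delicatula;Hyalosira_tropicalis;Rhabdonema_minutum;Cyclophora_tenuis;Pseudohimantidium_pacificum;Cymatosira_belgica;Odontella_sinensis;Cyclotella_meneghiniana;Stephanodiscus_sp;Skeletonema_tropicum;Thalassiosira_nordenskioeldii;Eunotogramma_laevis;Aulacoseira_granulata;Stephanopyxis_turris;Hyalodiscus_scoticus
Diatoms crown node	crown	160	267	secondary	Anomoeoneis_sculpta;Cymbella_aspera;Cymbella_helvetica;Cymbella_mexicana;Cymbella_proxima;Cymbella_tumida;Cymbopleura_inaequalis;Cymbopleura_naviculiformis;Didymosphenia_dentata;Didymosphenia_siberica;Didymosphenia_geminata;Gomphoneis_minuta;Gomphonema_clevei;Mayamaea_atomus;Pinnularia_acuminata;Pinnularia_altiplanensis;Pinnularia_grunowii;Pinnularia_microstauron;Pinnularia_nodosa;Pinnularia_sp;Pinnularia_subcommutata;Pinnularia_viridiforme;Pinnularia_viridiformis;Sellaphora_blackfordensis;Cocconeis_stauroneiformis;Fragilaria_bidens;Pteroncola_inane;Nanofrustulum_shiloi;Opephora_sp;Pseudostaurosira_brevistriata;Licmophora_paradoxa;Tabularia_laevis;Diatoma_moniliforme;Thalassiothrix_longissima;Dimeregramma_minor;Rhaphoneis_sp;Plagiostriata_goreensis;Grammatophora_marina;Hyalosira_delicatula;Hyalosira_tropicalis;Rhabdonema_minutum;Cyclophora_tenuis;Pseudohimantidium_pacificum;Cymatosira_belgica;Odontella_sinensis;Cyclotella_meneghiniana;Stephanodiscus_sp;Skeletonema_tropicum;Thalassiosira_nordenskioeldii;Eunotogramma_laevis;Aulacoseira_granulata;Stephanopyxis_turris;Hyalodiscus_scoticus
Mediophyceae stem node	stem		267	-	Cymatosira_belgica;Odontella_sinensis;Cyclotella_meneghiniana;Stephanodiscus_sp;Skeletonema_tropicum;Thalassiosira_nordenskioeldii;Eunotogramma_laevis
Mediophyceae stem node	stem	110		fossil	Cymatosira_belgica;Odontella_sinensis;Cyclotella_meneghiniana;Stephanodiscus_sp;Skeletonema_tropicum;Thalassiosira_nordenskioeldii;Eunotogramma_laevis
Bacillariophyceae crown node	crown	96.5	204	secondary	Anomoeoneis_sculpta;Cymbella_aspera;Cymbella_helvetica;Cymbella_mexicana;Cymbella_proxima;Cymbella_tumida;Cymbopleura_inaequalis;Cymbopleura_naviculiformis;Didymosphenia_dentata;Didymosphenia_siberica;Didymosphenia_geminata;Gomphoneis_minuta;Gomphonema_clevei;Mayamaea_atomus;Pinnularia_acuminata;Pinnularia_altiplanensis;Pinnularia_grunowii;Pinnularia_microstauron;Pinnularia_nodosa;Pinnularia_sp;Pinnularia_subcommutata;Pinnularia_viridiforme;Pinnularia_viridiformis;Sellaphora_blackfordensis;Cocconeis_stauroneiformis;Fragilaria_bidens;Pteroncola_inane;Nanofrustulum_shiloi;Opephora_sp;Pseudostaurosira_brevistriata;Licmophora_paradoxa;Tabularia_laevis;Diatoma_moniliforme;Thalassiothrix_longissima;Dimeregramma_minor;Rhaphoneis_sp;Plagiostriata_goreensis;Grammatophora_marina;Hyalosira_delicatula;Hyalosira_tropicalis;Rhabdonema_minutum;Cyclophora_tenuis;Pseudohimantidium_pacificum
Core araphids/raphids split	crown	93.8	185	secondary	Anomoeoneis_sculpta;Cymbella_aspera;Cymbella_helvetica;Cymbella_mexicana;Cymbella_proxima;Cymbella_tumida;Cymbopleura_inaequalis;Cymbopleura_naviculiformis;Didymosphenia_dentata;Didymosphenia_siberica;Didymosphenia_geminata;Gomphoneis_minuta;Gomphonema_clevei;Mayamaea_atomus;Pinnularia_acuminata;Pinnularia_altiplanensis;Pinnularia_grunowii;Pinnularia_microstauron;Pinnularia_nodosa;Pinnularia_sp;Pinnularia_subcommutata;Pinnularia_viridiforme;Pinnularia_viridiformis;Sellaphora_blackfordensis;Cocconeis_stauroneiformis;Fragilaria_bidens;Pteroncola_inane;Nanofrustulum_shiloi;Opephora_sp;Pseudostaurosira_brevistriata;Licmophora_paradoxa;Tabularia_laevis;Diatoma_moniliforme;Thalassiothrix_longissima;Dimeregramma_minor;Rhaphoneis_sp
Raphid pennates crown	crown	70	165	secondary	Anomoeoneis_sculpta;Cymbella_aspera;Cymbella_helvetica;Cymbella_mexicana;Cymbella_proxima;Cymbella_tumida;Cymbopleura_inaequalis;Cymbopleura_naviculiformis;Didymosphenia_dentata;Didymosphenia_siberica;Didymosphenia_geminata;Gomphoneis_minuta;Gomphonema_clevei;Mayamaea_atomus;Pinnularia_acuminata;Pinnularia_altiplanensis;Pinnularia_grunowii;Pinnularia_microstauron;Pinnularia_nodosa;Pinnularia_sp;Pinnularia_subcommutata;Pinnularia_viridiforme;Pinnularia_viridiformis;Sellaphora_blackfordensis;Cocconeis_stauroneiformis
Pinnularia stem node	stem		100	secondary	Pinnularia_acuminata;Pinnularia_altiplanensis;Pinnularia_grunowii;Pinnularia_microstauron;Pinnularia_nodosa;Pinnularia_sp;Pinnularia_subcommutata;Pinnularia_viridiforme;Pinnularia_viridiformis
Pinnularia stem node	stem	40		fossil	Pinnularia_acuminata;Pinnularia_altiplanensis;Pinnularia_grunowii;Pinnularia_microstauron;Pinnularia_nodosa;Pinnularia_sp;Pinnularia_subcommutata;Pinnularia_viridiforme;Pinnularia_viridiformis
Didymosphenia crown node	crown		70	geological	Didymosphenia_dentata;Didymosphenia_siberica;Didymosphenia_geminata
Didymosphenia crown node	crown	7.3		fossil	Didymosphenia_dentata;Didymosphenia_siberica;Didymosphenia_geminata
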