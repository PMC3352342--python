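virus_strain	host_species
NAKV	Mansonia_africana
CxFV_Tokyo	Culex_pipiens
CxFV_Japan03	Culex_pipiens
CxFV_HOU24518	Culex_quinquefasciatus
CxFV_Iowa07	Culex_pipiens
CxFV_Mexico07	Culex_quinquefasciatus
CxFV_Uganda08	Culex_quinquefasciatus
QBV	Culex_quinquefasciatus
CFAV_Culebra	Stegomyia_aegypti
CFAV_Cammisa	Stegomyia_aegypti
AeFV	Stegomyia_albopicta
KRV_SR75	Neomelaniconion_mcintoshi
KRV_SR82	Neomelaniconion_mcintoshi
DENV1	Stegomyia_aegypti
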