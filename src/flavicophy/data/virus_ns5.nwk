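(DENV1,((((CFAV_Culebra,CFAV_Cammisa),AeFV),(KRV_SR75,KRV_SR82)),(NAKV,(QBV,(((CxFV_Tokyo,CxFV_Japan03),(CxFV_Iowa07,CxFV_HOU24518)),(CxFV_Mexico07,CxFV_Uganda08))))));
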