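# The 12 FDA-approved pulmonary-hypertension drugs, as published.
Adcirca
Adempas
Ambrisentan
Bosentan
Epoprostenol
Iloprost
Macitentan
Orenitram
Remodulin
Sildenafil
Tyvaso
Uptravi
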