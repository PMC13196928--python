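# Brand -> active-substance synonyms needed to align the published top-30
# lists with the generically named pulmonary-hypertension panel.
# Treprostinil products (Tyvaso, Remodulin, Orenitram) are deliberately
# kept as distinct canonical names, matching their distinct published rows.
OPSUMIT	MACITENTAN
ADEMPAS	RIOCIGUAT
ADCIRCA	TADALAFIL
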