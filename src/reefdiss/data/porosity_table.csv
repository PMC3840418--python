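family,n_species,porosity
Acroporidae,271,perforate
Agariciidae,45,imperforate
Astrocoeniidae,15,imperforate
Caryophylliidae,7,imperforate
Dendrophylliidae,19,imperforate
Euphyllidae,17,imperforate
Faviidae,130,imperforate
Fungiidae,46,imperforate
Meandrinidae,12,imperforate
Merulinidae,12,imperforate
Mussidae,52,imperforate
Oculinidae,16,imperforate
Pectiniidae,29,imperforate
Pocilloporidae,31,imperforate
Poritidae,101,perforate
Siderastreidae,32,perforate
Trachphylliidae,1,imperforate
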