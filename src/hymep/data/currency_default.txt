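# Default currency-metabolite exclusion list (KEGG compound ids).
# These ubiquitous cofactors and inorganics are ignored when deciding
# whether two reactions are metabolically linked; they remain part of
# every reaction's stoichiometry.
C00001  # H2O
C00002  # ATP
C00008  # ADP
C00020  # AMP
C00009  # orthophosphate
C00013  # diphosphate
C00003  # NAD+
C00004  # NADH
C00006  # NADP+
C00005  # NADPH
C00016  # FAD
C01352  # FADH2
C00010  # coenzyme A
C00080  # H+
C00007  # O2
C00014  # NH3
C00011  # CO2
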