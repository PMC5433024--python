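# SYNTHETIC PAM activity factors (CFD-shaped placeholder, not published
# values). Keys are IUPAC masks tried in file order; first match wins.
pam	factor
NGG	1.0
NAG	0.25
NGA	0.07
NCG	0.11
NTG	0.04
NNN	0.0
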