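# Salt / counter-ion / hydrate suffixes stripped during compound-name
# normalization. One suffix per line, matched case-insensitively at the end
# of an already lower-cased, whitespace-collapsed name; stripping repeats
# until no suffix matches. Lines starting with '#' are comments.
hydrochloride
dihydrochloride
trihydrochloride
hydrobromide
hcl
potassium salt
dipotassium salt
sodium salt
disodium salt
trisodium salt
calcium salt
magnesium salt
ammonium salt
lithium salt
zinc salt
hydrate
monohydrate
dihydrate
trihydrate
hemihydrate
sesquihydrate
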