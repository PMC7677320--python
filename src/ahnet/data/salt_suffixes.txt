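# Salt / hydrate suffixes stripped during drug-name canonicalization.
# One suffix per line; matched case-insensitively as trailing words.
hydrochloride
dihydrochloride
hydrobromide
mesylate
besylate
maleate
fumarate
tartrate
succinate
citrate
acetate
sodium
potassium
calcium
sulfate
sulphate
phosphate
nitrate
monohydrate
dihydrate
hemihydrate
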