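# Vogel's minimal medium N with sucrose, as uptake metabolites.
# role "carbon" marks the limiting carbon source (capped at 1.5 mmol/gDW/h
# by default); every other component is treated as non-limiting.
metabolite_id	role
SUCROSE[e]	carbon
AMMONIUM[e]	nitrogen
NITRATE[e]	nitrogen
Pi[e]	phosphate
SULFATE[e]	sulfur
CIT[e]	chelator
BIOTIN[e]	vitamin
MG+2[e]	salt
CA+2[e]	salt
NA+[e]	salt
K+[e]	salt
CL-[e]	salt
ZN+2[e]	trace
FE+2[e]	trace
CU+2[e]	trace
MN+2[e]	trace
WATER[e]	solvent
OXYGEN-MOLECULE[e]	gas
PROTON[e]	ion
CARBON-DIOXIDE[e]	gas
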