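# Default chemical-component classification for photosystem supercomplex models.
# Format: comp_id: category  or  comp_id: "category:display name".
# User files loaded with ComponentMap.from_file override these entries per key.
#
# Deposited code vocabularies for cryptophyte carotenoids vary between entries,
# so this map is data, not code: extend or override it for your files.

# chlorophylls
CLA: "chl_a:chlorophyll a"
CHL: "chl_a:chlorophyll a (alt code)"
KC1: "chl_c:chlorophyll c1"
KC2: "chl_c:chlorophyll c2"

# carotenoids
BCR: "carotenoid:beta-carotene"
ECH: "carotenoid:echinenone"
LUT: "carotenoid:lutein"
XAT: "carotenoid:violaxanthin"
ALX: "carotenoid:alloxanthin"
CRX: "carotenoid:crocoxanthin"
MON: "carotenoid:monadoxanthin"
ACR: "carotenoid:alpha-carotene"

# thylakoid lipids
LHG: "lipid:phosphatidylglycerol (PG)"
PG:  "lipid:phosphatidylglycerol (PG)"
LMG: "lipid:monogalactosyldiacylglycerol (MGDG)"
DGD: "lipid:digalactosyldiacylglycerol (DGDG)"
SQD: "lipid:sulfoquinovosyldiacylglycerol (SQDG)"

# metal clusters and ions
SF4: "fes_cluster:Fe4S4 cluster"
FES: "fes_cluster:Fe2S2 cluster"
OEX: "ion:Mn4CaO5 cluster"
MG:  "ion:magnesium ion"
CA:  "ion:calcium ion"
CL:  "ion:chloride ion"
FE:  "ion:iron ion"
MN:  "ion:manganese ion"

# waters and detergents
HOH: "water:water"
DOD: "water:heavy water"
LMT: "detergent:dodecyl-beta-D-maltoside"
LMU: "detergent:dodecyl-alpha-D-maltoside"
BNG: "detergent:nonyl glucoside"
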