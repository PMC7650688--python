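symbol	transcript	evidence_tier	inheritance_hint
ABCC8	NM_000352.4	candidate	AD
ACVRL1	NM_000020.3	established	AD
BMPR1B	NM_001203.3	candidate	AD
BMPR2	NM_001204.6	established	AD
CAV1	NM_001753.5	established	AD
CBLN2	NM_182511.3	candidate	AD
CPS1	NM_001122633.2	candidate	either
EIF2AK4	NM_001013703.3	established	AR
ENG	NM_001114753.3	established	AD
GDF2	NM_016204.4	established	AD
KCNA5	NM_002234.4	candidate	AD
KCNK3	NM_002246.3	established	AD
MMACHC	NM_015506.3	candidate	AR
NOTCH3	NM_000435.2	candidate	AD
SARS2	NM_017827.3	candidate	AR
SMAD1	NM_005900.2	candidate	AD
SMAD4	NM_005359.6	candidate	AD
SMAD5	NM_001001420.2	candidate	AD
SMAD9	NM_005905.6	established	AD
TBX4	NM_018488.3	established	AD
TOPBP1	NM_007027.4	candidate	AD
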