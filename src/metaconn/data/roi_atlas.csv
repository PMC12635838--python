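name,network,x,y,z
ACC,SN,0,22,35
LAINS,SN,-44,13,1
RAINS,SN,47,14,0
MPFC,DMN,0,48,-18
LLP,DMN,-39,-77,33
RLP,DMN,47,-67,29
Precuneus,DMN,0,-49,40
LLPFC,CEN,-43,33,28
RLPFC,CEN,41,38,30
LPPC,CEN,-46,-58,49
RPPC,CEN,52,-52,45
PCC,ToM,0,-52,22
LSTS,ToM,-58,-48,7
RSTS,ToM,58,-44,8
LTPJ,ToM,-58,-58,22
RTPJ,ToM,58,-52,20
LIFG,ToM,-48,14,26
RIFG,ToM,48,14,26
LANG,ToM,-46,-72,31
RANG,ToM,48,-69,31
LCEREB,ToM,-20,-72,-36
RCEREB,ToM,20,-72,-36
LIPC,ToM,-45,-46,53
RIPC,ToM,52,-42,50
VLPFC,ToM,42,46,0
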