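abbrev,expansion
v,victim
vic,victim
s,suspect
sus,suspect
susp,suspect
gsw,gunshot wound
gsws,gunshot wounds
le,law enforcement
leo,law enforcement officer
pd,police department
ofc,officer
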