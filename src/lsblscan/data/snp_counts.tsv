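set	n_snps
total	5140908
wild	4321515
local	4491942
commercial	3746643
shared	2832649
wild_unique	135613
local_unique	222579
commercial_unique	195701
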