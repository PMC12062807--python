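population	breed	count	type
wild	Mallard	72	wild
local	JinDing duck	11	egg
local	Liancheng White duck	3	egg
local	Mawang duck	3	egg
local	Putian black duck	3	egg
local	Sansui duck	3	egg
local	Shanma duck	21	egg
local	Shaoxing duck	24	egg
local	Taiwan duck	3	egg
local	Youxian duck	3	egg
local	Yulin-Wu duck	9	dual
local	Donglan duck	9	dual
local	Gaoyou duck	11	dual
local	Ji'an red duck	3	dual
local	Longsheng-Cui duck	13	dual
local	Wenqiao duck	10	dual
local	Rongshui-Xiang duck	10	dual
local	Xilin-Ma duck	10	dual
local	Yulin-Ma duck	10	dual
commercial	Pekin duck	160	meat
commercial	Mapleleaf duck	7	meat
commercial	CherryValley duck	18	meat
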