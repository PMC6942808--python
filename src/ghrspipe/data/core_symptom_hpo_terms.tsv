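symptom	terms
Red lips	HP:0000214
Red tongue	HP:0000227
Yellow fur
Thick fur
Feverish feeling in palms and soles
Slippery pulse
Halitosis	HP:0100812
Abnormal appetite	HP:0002591,HP:0004396,HP:0011968,HP:0002039
Belching
Vomiting	HP:0002013
Reduced frequency of defecation	HP:0002019
Dry stool	HP:0002019
Hard defecation	HP:0002019
Smelly stool
Yellow urine	HP:0012086
Sweating at night	HP:0030166
Restlessness at night sleep	HP:0002360,HP:0003763
Vexation and irritability	HP:0000711,HP:0100754
Worse after improper diet
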