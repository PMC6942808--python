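item,mean_score,variable_coefficient,full_mark_rate,deleted
Red complexion,2.94,0.22,16.67,0
Aversion to heat,2.61,0.35,14.81,0
Head sweating,2.78,0.27,16.67,0
Sweating at night,2.37,0.36,12.96,0
Feverish feeling in palms and soles,3.48,0.20,57.41,0
Eye discharge,2.56,0.27,5.56,0
Epistaxis,2.19,0.33,3.70,0
Hardened mucus in the nose,1.89,0.41,0.00,1
Red lips,3.54,0.17,59.26,0
Gingival swelling,2.78,0.29,18.52,0
Gingival pain,2.50,0.35,11.11,0
Halitosis,3.69,0.15,72.22,0
Hot mouth and nasal breath,3.24,0.17,29.63,0
Mouth sores,3.07,0.21,24.07,0
Thirst with preference for cold drink,3.30,0.16,33.33,0
Abnormal appetite (enormous or poor),3.15,0.24,35.19,0
Belching,2.24,0.34,7.41,0
Acid regurgitation,1.83,0.46,3.70,1
Vomiting with smell,2.78,0.32,22.22,0
Distending pain in the abdomen and gastric cavity,2.63,0.31,12.96,0
Umbilical or gastric tenderness,2.11,0.40,5.56,0
Smelly flatus,3.54,0.16,57.41,0
Dry stool,3.50,0.17,55.56,0
Hard defecation,3.02,0.25,25.93,0
Reduced frequency of defecation (>once per day),2.78,0.30,16.67,0
Indigestible food in the stool,1.87,0.54,7.41,1
Smelly stool,3.19,0.27,44.44,0
Susceptible to contract respiratory tract infection,2.65,0.28,11.11,0
Pharyngeal swelling,2.72,0.33,20.37,0
Pharyngalgia,2.43,0.35,9.26,0
Pre/postauricular swelling,1.61,0.47,0.00,1
Swelling of the submandibular lymph nodes,1.76,0.52,3.70,1
Cough,1.87,0.48,3.70,1
Expectoration,1.69,0.56,1.85,1
Phlegm wheezing in the throat,1.59,0.60,1.85,1
Vexation and irascibility,2.70,0.35,18.52,0
Restlessness on night sleep (hyperactivity odontoprisis and somniloquy),3.22,0.21,35.19,0
Hyperactivity of the limbs daytime,1.94,0.39,1.85,1
Motor tics or vocal tics,1.44,0.67,0.00,1
Yellow urine,2.93,0.25,22.22,0
Red tongue,3.67,0.15,70.37,0
Red dot on the tongue,2.94,0.31,27.78,0
Yellow fur,3.65,0.16,70.37,0
Thick fur,3.54,0.18,61.11,0
Rapid pulse,3.20,0.20,33.33,0
Slippery pulse,3.22,0.26,44.44,0
Worse after improper diet (crapulence or indulgence for greasy foods),3.35,0.21,48.15,0
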