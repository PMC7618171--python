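indicator,kind,band,lower,upper,points
hr_increase,numeric,0-4 bpm,0,5,0
hr_increase,numeric,5-14 bpm,5,15,1
hr_increase,numeric,15-24 bpm,15,25,2
hr_increase,numeric,>=25 bpm,25,inf,3
spo2_decrease,numeric,0-2.4 %,0,2.5,0
spo2_decrease,numeric,2.5-4.9 %,2.5,5,1
spo2_decrease,numeric,5-7.4 %,5,7.5,2
spo2_decrease,numeric,>=7.5 %,7.5,inf,3
facial_fraction,numeric,none (<9%),0,0.09,0
facial_fraction,numeric,minimal (9-39%),0.09,0.40,1
facial_fraction,numeric,moderate (40-69%),0.40,0.70,2
facial_fraction,numeric,maximal (>=70%),0.70,inf,3
gestational_age,numeric_desc,>=36 wk,36,inf,0
gestational_age,numeric_desc,32-35+6 wk,32,36,1
gestational_age,numeric_desc,28-31+6 wk,28,32,2
gestational_age,numeric_desc,<28 wk,0,28,3
behavioural_state,categorical,active_awake,,,0
behavioural_state,categorical,quiet_awake,,,1
behavioural_state,categorical,active_asleep,,,2
behavioural_state,categorical,quiet_asleep,,,3
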