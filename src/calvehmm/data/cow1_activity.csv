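animal_id,hour_offset,posture_changes
cow1,-72,2
cow1,-71,2
cow1,-70,5
cow1,-69,6
cow1,-68,1
cow1,-67,2
cow1,-66,1
cow1,-65,0
cow1,-64,0
cow1,-63,2
cow1,-62,2
cow1,-61,2
cow1,-60,2
cow1,-59,1
cow1,-58,2
cow1,-57,2
cow1,-56,1
cow1,-55,0
cow1,-54,0
cow1,-53,0
cow1,-52,1
cow1,-51,1
cow1,-50,2
cow1,-49,1
cow1,-48,2
cow1,-47,4
cow1,-46,2
cow1,-45,3
cow1,-44,1
cow1,-43,2
cow1,-42,1
cow1,-41,0
cow1,-40,1
cow1,-39,2
cow1,-38,2
cow1,-37,1
cow1,-36,4
cow1,-35,1
cow1,-34,2
cow1,-33,1
cow1,-32,0
cow1,-31,0
cow1,-30,0
cow1,-29,1
cow1,-28,4
cow1,-27,2
cow1,-26,3
cow1,-25,0
cow1,-24,3
cow1,-23,3
cow1,-22,4
cow1,-21,2
cow1,-20,4
cow1,-19,2
cow1,-18,2
cow1,-17,0
cow1,-16,0
cow1,-15,0
cow1,-14,0
cow1,-13,4
cow1,-12,2
cow1,-11,0
cow1,-10,1
cow1,-9,1
cow1,-8,2
cow1,-7,2
cow1,-6,2
cow1,-5,6
cow1,-4,2
cow1,-3,2
cow1,-2,5
cow1,-1,13
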