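RULE JUMP
#: Vertical movement of the head changes at least 5cm in under 1 second
DISP head Y ABS>= 0.05 WITHIN 1.0
AND
#: Vertical movement of the left ankle changes at least 5 cm in under 1 second
DISP ankle_left Y ABS>= 0.05 WITHIN 1.0
AND
#: Vertical movement of the right ankle changes at least 5 cm in under 1 second
DISP ankle_right Y ABS>= 0.05 WITHIN 1.0
AND
#: Vertical movement of the hip centre changes at least 5cm in under 1 second
DISP hip_centre Y ABS>= 0.05 WITHIN 1.0
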