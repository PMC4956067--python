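RULE SIDESTEP
#: Horizontal Movement of the hip centre changes at least 10 cm in under .5 seconds
DISP hip_centre X ABS>= 0.1 WITHIN 0.5
AND
#: Horizontal movement of the right foot changes at least 30 centimetres in under .3 seconds
DISP foot_right X ABS>= 0.3 WITHIN 0.3
AND
#: Horizontal movement of the shoulder centre changes at least 10 centimetres in under .5 seconds
DISP shoulder_centre X ABS>= 0.1 WITHIN 0.5
OR
#: Horizontal Movement of the hip centre changes at least 10 cm in under .5 seconds
DISP hip_centre X ABS>= 0.1 WITHIN 0.5
AND
#: Horizontal movement of the left foot changes at least 30 centimetres in under .3 seconds
DISP foot_left X ABS>= 0.3 WITHIN 0.3
AND
#: Horizontal movement of the shoulder centre changes at least 10 centimetres in under .5 seconds
DISP shoulder_centre X ABS>= 0.1 WITHIN 0.5
AND
#: Horizontal movement of the right foot changes less than -25 centimetres in under .5 seconds
DISP foot_right X <= -0.25 WITHIN 0.5
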