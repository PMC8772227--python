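group,test,mean_z,sd_z
C9orf72,camel_cactus,-1.81,2.81
C9orf72,boston_naming,-1.77,3.32
C9orf72,category_fluency,-1.20,1.05
C9orf72,digit_span_forward,-0.39,1.19
C9orf72,tmt_a,-1.37,2.17
C9orf72,digit_symbol,-1.18,1.30
C9orf72,cwit_colour,-2.85,3.58
C9orf72,cwit_word,-1.86,3.11
C9orf72,digit_span_backward,-0.53,1.23
C9orf72,tmt_b,-2.44,2.95
C9orf72,cwit_ink,-3.46,3.91
C9orf72,phonemic_fluency,-1.18,1.18
C9orf72,benson_copy,-0.90,1.90
C9orf72,benson_recall,-0.72,1.57
C9orf72,fcsrt_free,-1.68,1.36
C9orf72,fcsrt_total,-2.20,3.56
C9orf72,fcsrt_delayed_free,-1.59,1.59
C9orf72,fcsrt_delayed_total,-2.10,3.81
C9orf72,facial_emotion,-1.67,1.87
GRN,camel_cactus,-0.57,1.36
GRN,boston_naming,-0.68,1.62
GRN,category_fluency,-0.54,1.04
GRN,digit_span_forward,-0.08,1.26
GRN,tmt_a,-0.69,1.63
GRN,digit_symbol,-0.62,1.23
GRN,cwit_colour,-0.52,1.85
GRN,cwit_word,-0.02,1.46
GRN,digit_span_backward,-0.49,1.23
GRN,tmt_b,-1.81,3.06
GRN,cwit_ink,-1.13,2.21
GRN,phonemic_fluency,-0.08,1.33
GRN,benson_copy,-0.06,1.16
GRN,benson_recall,-0.75,1.46
GRN,fcsrt_free,-0.72,1.49
GRN,fcsrt_total,-1.42,3.05
GRN,fcsrt_delayed_free,-0.97,1.58
GRN,fcsrt_delayed_total,-1.13,3.09
GRN,facial_emotion,-1.00,1.47
MAPT,camel_cactus,-2.10,3.08
MAPT,boston_naming,-2.63,3.16
MAPT,category_fluency,-0.84,1.14
MAPT,digit_span_forward,0.13,1.23
MAPT,tmt_a,-0.72,1.54
MAPT,digit_symbol,-0.67,1.31
MAPT,cwit_colour,-1.30,2.17
MAPT,cwit_word,-0.54,1.47
MAPT,digit_span_backward,-0.19,0.98
MAPT,tmt_b,-1.37,2.58
MAPT,cwit_ink,-1.16,2.54
MAPT,phonemic_fluency,-0.64,1.28
MAPT,benson_copy,-0.46,1.39
MAPT,benson_recall,-1.27,1.91
MAPT,fcsrt_free,-1.71,1.80
MAPT,fcsrt_total,-2.86,3.62
MAPT,fcsrt_delayed_free,-1.72,2.04
MAPT,fcsrt_delayed_total,-2.82,4.02
MAPT,facial_emotion,-1.04,1.59
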