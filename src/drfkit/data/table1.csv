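step_mm,measured_n,predicted_n,abs_error_n
5,58.4,50.32,8.08
10,105.2,95.89,9.31
15,154.0,148.35,5.65
20,215.6,210.10,5.50
30,345.2,348.50,3.30
40,485.5,482.10,3.40
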