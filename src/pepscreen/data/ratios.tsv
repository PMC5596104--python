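name	numerator	denominator
IL10/TNFα	IL-10	TNFα
IL10/IFNγ	IL-10	IFNγ
IL10/IL17	IL-10	IL-17A
IL10/IL4	IL-10	IL-4
IFNγ/IL17	IFNγ	IL-17A
Th1/Th2	Th1	Th2
Th17/Th1	Th17	Th1
Th17/Th2	Th17	Th2
Th1/Treg	Th1	Treg
Th2/Treg	Th2	Treg
Th1+Th2+Th17/Treg	Th1+Th2+Th17	Treg
Th17/Treg	Th17	Treg
Th22/Th1	Th22	Th1
Th22/Th2	Th22	Th2
Th22/Th17	Th22	Th17
Th22/Treg	Th22	Treg
Th22+Th17/Th1+Th2	Th22+Th17	Th1+Th2
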