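subset	cytokines
Th1	IL-12p70,IL-18,IFNγ
Th2	IL-4,IL-5,IL-13
Th9	IL-9
Th17	IL-1β,IL-6,IL-23,IL-21,IL-17A
Th22	IL-22
Treg	IL-10
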