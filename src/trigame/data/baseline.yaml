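# Baseline model constants (monetary values in CNY per mask).
R: 0.8
H: 1.8
GC: 2
GH: 0.2
P: 1
C: 0.5
CG: 0.05
CS: 0.3
d: 0.05
rc: 2
f1: 0.1
f2: 0.2
q: 1
alpha: 1.5
beta: 1.5
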