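name,Rp,Rd,C
Right Coronary Artery,5.42e8,7.17e9,2.12e-10
Left Coronary Artery,5.42e8,7.17e9,2.12e-10
Right Subclavian Artery,7.79e7,1.03e9,1.47e-9
Right Common Carotid Artery,7.38e7,9.76e8,1.55e-9
Left Common Carotid Artery,1.21e8,1.61e9,9.45e-10
Left Subclavian Artery,1.06e8,1.41e9,1.08e-9
Descending Aorta,2.01e7,2.66e8,5.70e-9
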