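group,finished,failed
Breast,16,88
Colorectal,5,15
Endometrial,1,10
Head and neck,2,9
Lung,109,264
Melanoma,1,6
Pancreatic/gallbladder,6,10
Thyroid,4,10
Unknown,4,8
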