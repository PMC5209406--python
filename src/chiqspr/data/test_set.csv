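name,logcmc
12-Py(2)-4-(2)Py-12,-2.89279
p-[C14H29N+(CH3)2CH2CH(OH)CH2O]2C6H4,-4.0
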