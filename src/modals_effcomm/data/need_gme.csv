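force,flavor,probability
weak,epistemic,0.139
weak,deontic,0.042
weak,circumstantial,0.143
strong,epistemic,0.104
strong,deontic,0.254
strong,circumstantial,0.318
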