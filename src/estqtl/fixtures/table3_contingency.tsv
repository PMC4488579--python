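zone	total	annotated	stress
outside	1557	1104	160
inside	349	243	85
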