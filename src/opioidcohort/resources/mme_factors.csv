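drug_base,mme_per_mg
codeine,0.15
hydrocodone,1.0
hydromorphone,4.0
morphine,1.0
oxycodone,1.5
tramadol,0.1
other,1.0
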