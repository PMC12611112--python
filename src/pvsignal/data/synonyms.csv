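verbatim,canonical
penicillamine,penicillamine
d-penicillamine,penicillamine
penicilamine,penicillamine
cuprimine,penicillamine
depen,penicillamine
trientine,trientine
trientine hcl,trientine
trientine hydrochloride,trientine
syprine,trientine
cuprior,trientine
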