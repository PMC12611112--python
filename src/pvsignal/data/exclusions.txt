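# Adverse-event preferred terms excluded from final signal tables, one
# case-insensitive substring pattern per line.  Covers product-quality
# problems, drug-use issues and terms that restate the treated indication
# rather than describe an adverse event.  Edit freely; the list is applied
# after screening so every exclusion is auditable in the excluded-signals
# output.
off label use
product dose omission
product use issue
product quality issue
product substitution issue
drug ineffective
therapeutic response decreased
therapy interrupted
treatment noncompliance
intentional product misuse
accidental overdose
overdose
medication error
wilson's disease
hepatolenticular degeneration
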