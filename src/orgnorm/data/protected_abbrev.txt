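# Words whose trailing period never ends a sentence (matched casefolded,
# period stripped).  Single capital letters (genus initials) are protected
# by rule, not listed here.
al
et
e.g
i.e
vs
cf
ca
approx
fig
figs
subsp
spp
sp
var
ser
st
no
dr
etc
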