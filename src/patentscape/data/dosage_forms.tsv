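form	term
solution	solution
solution	aqueous solution
tablet	tablet
powder	powder
gel	gel
gel	hydrogel
suspension	suspension
emulsion	emulsion
ointment	ointment
suppository	suppository
patch	patch
patch	transdermal patch
lozenge	lozenge
chewing gum	chewing gum
chewing gum	medicated gum
fiber	fiber
fiber	nanofiber
sheet	sheet
capsule	capsule
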