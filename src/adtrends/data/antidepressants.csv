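product_name,drug_class
citalopram,SSRI
escitalopram,SSRI
fluoxetine,SSRI
fluvoxamine,SSRI
paroxetine,SSRI
sertraline,SSRI
amitriptyline,TCA
clomipramine,TCA
dosulepin,TCA
doxepin,TCA
imipramine,TCA
lofepramine,TCA
nortriptyline,TCA
trimipramine,TCA
agomelatine,OTHER
duloxetine,OTHER
mirtazapine,OTHER
moclobemide,OTHER
phenelzine,OTHER
reboxetine,OTHER
trazodone,OTHER
venlafaxine,OTHER
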