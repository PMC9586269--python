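class_label	keywords
IDS/prenyltransferase	isoprenyl diphosphate synthase,prenyltransferase,geranyl diphosphate synthase,farnesyl diphosphate synthase,geranylgeranyl diphosphate synthase
phosphatase	phosphatase
P450 reductase	p450 reductase,cytochrome p450 reductase
cytochrome P450	cytochrome p450,p450
oxidase/reductase	oxidase,oxidoreductase,dehydrogenase,reductase
transporter	transporter,transport protein,carrier
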