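# Default functional-consequence severity table (Sequence Ontology term -> score).
# Stand-in values ordered monotonically by predicted deleteriousness, from
# transcript ablation / protein-truncating near 1.0 down to intergenic at 0.05.
# Fully overridable: pass any two-column TSV of the same shape via the config.
SO:0001893	1.0
SO:0001589	0.95
SO:0001587	0.95
SO:0001574	0.95
SO:0001575	0.95
SO:0001578	0.9
SO:0002012	0.9
SO:0001583	0.7
SO:0001821	0.7
SO:0001822	0.7
SO:0001630	0.65
SO:0001060	0.5
SO:0001819	0.35
SO:0001623	0.2
SO:0001624	0.2
SO:0001627	0.1
SO:0001631	0.1
SO:0001632	0.1
SO:0001628	0.05
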