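# Declarative comparison groups for iterative concatenation, in the shape
# used for curated seagrass/saltmarsh analyses: a baseline voucher and
# labelled member sets at increasing taxonomic distance. Sample ids must
# exist in the database the groups are applied to; the ones below match the
# synthetic study of example 06 (seed 31).
baseline: Sp01_01_01_Loc01
groups:
  - label: within species
    category: within species
    members: [Sp01_01_01_Loc02]
  - label: within genus
    category: within genus
    members: [Sp01_01_02_Loc01, Sp01_01_02_Loc02]
  - label: within family
    category: within family
    members: [Sp01_02_01_Loc01, Sp01_02_02_Loc01]
  - label: between family
    category: between family
    members: [Sp02_01_01_Loc01, Sp02_02_01_Loc01]
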