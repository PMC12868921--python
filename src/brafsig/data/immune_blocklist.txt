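# Default coarse immune-lineage blocklist applied when pruning founder
# gene sets.  One gene symbol per line; '#' starts a comment.  The list
# covers pan-leukocyte, T/B/NK, and myeloid lineage markers commonly used
# to flag immune-compartment expression; it is editable and replaceable
# via the --blocklist option.
PTPRC
CD2
CD3D
CD3E
CD3G
CD4
CD8A
CD8B
IL7R
CCL5
GZMA
GZMB
GZMK
PRF1
NKG7
GNLY
KLRD1
NCR1
CD19
MS4A1
CD79A
CD79B
IGHM
JCHAIN
CD14
FCGR3A
FCGR3B
ITGAM
ITGAX
LYZ
CST7
CSF1R
CD68
CD163
MRC1
AIF1
FCER1G
TYROBP
LCP1
CORO1A
CXCR4
CCR7
SELL
IL2RB
IL2RG
TRAC
TRBC1
TRBC2
HLA-DRA
HLA-DRB1
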