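# Semaphorin/plexin signaling family gene list (29 genes) used as the
# pathway-family denominator for co-mutation enrichment. This is a curated
# stand-in assembled from the human semaphorin (SEMA3-7) and plexin
# (PLXNA/B/C/D) gene families; replace with a custom list via --family-file.
SEMA3A
SEMA3B
SEMA3C
SEMA3D
SEMA3E
SEMA3F
SEMA3G
SEMA4A
SEMA4B
SEMA4C
SEMA4D
SEMA4F
SEMA4G
SEMA5A
SEMA5B
SEMA6A
SEMA6B
SEMA6C
SEMA6D
SEMA7A
PLXNA1
PLXNA2
PLXNA3
PLXNA4
PLXNB1
PLXNB2
PLXNB3
PLXNC1
PLXND1
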