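# Terms whose case-insensitive presence in an ORF function label marks it
# as an unambiguous phage-related gene.  One term per line; '#' comments.
capsid
terminase
tail
portal
integrase
holin
lysin
lysozyme
baseplate
phage
prophage
virion
head-tail
antirepressor
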