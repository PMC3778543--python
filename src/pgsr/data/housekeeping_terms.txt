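# Terms marking functions commonly associated with chromosomal (host)
# sequences.  One term per line; '#' comments.
ribosomal
ABC transporter
tRNA
elongation factor
gyrase
topoisomerase
dehydrogenase
permease
aminotransferase
synthetase
two-component
cell division
peptidoglycan
glycosyltransferase
efflux
sigma factor
chemotaxis
flagellar
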