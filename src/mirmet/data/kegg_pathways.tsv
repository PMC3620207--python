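pathway	number_of_genes	gene_ids	p_value
Pathways in cancer	18	8322 1871 324 598 867 2113 5156 5925 998 10000 4286 3479 596 861 3815 5594 6774 6789	1.23E-11
MAPK signaling pathway	13	55970 4149 1848 23162 5578 5495 5156 5606 3727 3725 5880 6788 5062	2.46E-15
Wnt signaling pathway	20	6423 1460 5578 3725 595 56998 5880 4775 6424 896 8313 166336 2932 5527 27101 4776 9475 1487 818 5567	5.77E-09
Small cell lung cancer	12	595 10401 5743 5925 4149 207 1284 10000 331 1163 1027 3918	2.79E-06
Prostate cancer	8	596 5925 9586 5594 5156 10000 1871 3479	4.35E-07
TGF-beta signaling pathway	8	3398 6198 3400 90 659 5594 57154 4092	4.35E-07
Glioma	7	808 5925 5594 5156 10000 1871 3479	5.62E-07
NF-KappaB signaling pathway	14	595 3574 10401 163702 161742 207 10254 6778 10000 896 10379 81848 3977 9655	4.36E-05
Insulin signaling pathway	9	7248 10000 122809 808 2872 6198 867 1977 5594	5.62E-07
Pancreatic cancer	7	5925 598 998 6774 5594 10000 1871	8.25E-07
Melanoma	7	5925 5594 5156 10000 4286 1871 3479	8.25E-07
Chronic myeloid leukemia	7	5925 861 598 867 5594 10000 1871	9.55E-07
mTOR signaling pathway	6	7248 6198 5594 1977 10000 3479	1.89E-06
Acute myeloid leukemia	6	6198 861 6774 5594 3815 10000	3.67E-06
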