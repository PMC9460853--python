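# Population-average putative allele frequencies for nine wild fennel
# (Foeniculum vulgare) populations surveyed in Istria (Ankaran, Buje, Flengi,
# Liznjan, Padna, Plomin, Rabac, Rovinj, Vodnjan), as published for that survey.
# fp/fa: fenchone presence/absence allele frequencies (0/1/2 scoring over 2N
# haploid genomes); erc/arc: estragole / trans-anethole relative content at the
# putative phenylpropanoid locus; itsA/itsB/itsC: densitometric band-area
# fractions of the 684/529/344 bp MspI PCR-RFLP bands of the nrDNA ITS amplicon.
# *_sd columns are the across-plant sample standard deviations printed alongside
# the averages. Values transcribed at the published 3-decimal precision; ITS
# rows may sum to 0.999 from rounding and are renormalized on load.
population,fp,fa,erc,arc,itsA,itsB,itsC,fp_sd,erc_sd,itsA_sd,itsB_sd,itsC_sd
Ankaran,0.553,0.447,0.952,0.048,0.329,0.521,0.150,0.28,0.12,0.02,0.12,0.13
Buje,0.500,0.500,0.895,0.105,0.336,0.551,0.113,0.00,0.12,0.05,0.12,0.16
Flengi,0.526,0.474,0.597,0.403,0.352,0.648,0.000,0.20,0.37,0.03,0.03,0.00
Liznjan,0.471,0.529,0.730,0.270,0.324,0.619,0.057,0.12,0.28,0.03,0.07,0.09
Padna,0.667,0.333,0.922,0.078,0.330,0.670,0.000,0.25,0.12,0.03,0.03,0.00
Plomin,0.474,0.526,0.589,0.411,0.359,0.594,0.047,0.31,0.34,0.03,0.06,0.06
Rabac,0.725,0.275,0.003,0.997,0.383,0.540,0.076,0.26,0.01,0.05,0.08,0.11
Rovinj,0.425,0.575,0.849,0.151,0.398,0.498,0.104,0.29,0.23,0.06,0.09,0.14
Vodnjan,0.700,0.300,0.798,0.202,0.321,0.634,0.044,0.26,0.30,0.02,0.07,0.07
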