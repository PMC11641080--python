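"""Shared vocabulary: diagnostic classes, gene panel, treatment classes."""

#: Diagnostic classes: healthy controls, bipolar disorder, schizophrenia,
#: schizoaffective disorder.
DIAGNOSES = ("CTRL", "BD", "SZ", "SA")

#: The 8-gene targeted amplicon panel of blood RNA-editing genes.
GENES = ("CAMK1D", "GAB2", "IFNAR1", "KCNJ15", "LYN", "MDM2", "PDE8A", "PRKCB")

#: Five ATC psychotropic-treatment classes used as binary covariates.
TREATMENT_CLASSES = (
    "antipsychotics",
    "antidepressants",
    "anxiolytics",
    "antiepileptics",
    "hypnotics_sedatives",
)
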