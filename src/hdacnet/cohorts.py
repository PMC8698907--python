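"""Published top-15 RTK rankings from the public cohort analyses.

These are the top-15 RTK-coding genes ranked by HDAC SCORE in four
public expression cohorts — AML patients (GSE14468, N = 525),
neuroblastoma patients (GSE16476, N = 88), and the leukemia and
neuroblastoma cell-line panels of the Genomics of Drug Sensitivity in
Cancer resource.  They serve as reference inputs for cross-cohort
intersection: the genes high-scoring in every cohort are candidate
HDAC-dependent kinases.
"""

AML_PATIENT_TOP15 = (
    "TIE1", "KIT", "NTRK1", "IGF1R", "PTK7", "LTK", "FGFR3", "CSF1R",
    "DDR2", "AXL", "TEK", "INSRR", "ROR1", "AATK", "FLT3",
)

NB_PATIENT_TOP15 = (
    "NTRK1", "PDGFRA", "STYK1", "INSRR", "FLT4", "TIE1", "ROR2", "ROS1",
    "NTRK2", "FGFR2", "FGFR3", "CSF1R", "PDGFRB", "ALK", "KIT",
)

LEUKEMIA_CELL_LINE_TOP15 = (
    "FLT3", "NTRK1", "INSR", "RYK", "FGFR1", "MERTK", "ROR2", "FGFR3",
    "KIT", "RET", "ROR1", "PTK7", "DDR2", "DDR1", "CSF1R",
)

NB_CELL_LINE_TOP15 = (
    "NTRK1", "PDGFRA", "ALK", "AXL", "RET", "AATK", "ROR2", "TYRO3",
    "INSR", "DDR1", "NTRK3", "DDR2", "FGFR3", "FGFR1", "FLT3",
)

ALL_COHORT_TOP15 = {
    "aml_patients": AML_PATIENT_TOP15,
    "nb_patients": NB_PATIENT_TOP15,
    "leukemia_cell_lines": LEUKEMIA_CELL_LINE_TOP15,
    "nb_cell_lines": NB_CELL_LINE_TOP15,
}
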