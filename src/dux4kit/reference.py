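"""Reference sequences, gene panels, and analysis thresholds.

These are the fixed inputs of the DUX4 siRNA development workflow: the
luciferase-reporter target-site sequences used to probe target engagement
across species, the qPCR gene panels that define the FSHD composite score,
and the printed filtering thresholds of the differential-expression and
panel-selection steps.
"""

# Target-site sequences from the dual-luciferase reporter constructs
# (DNA, sense strand, 19 nt).  The cynomolgus site differs from the human
# site by a single nucleotide; the mutated site is an unrelated scramble.
HUMAN_TARGET_SITE = "CGACGGAGACTCGTTTGGA"
CYNO_TARGET_SITE = "CGAAGGAGACTCGTTTGGA"
MUTATED_TARGET_SITE = "ACAACAGACTTTAATGTAA"

# Human DUX4-regulated genes forming the 4-gene FSHD composite, and the
# two housekeeping reference genes used for normalization.
HUMAN_COMPOSITE_GENES = ("MBD3L2", "ZSCAN4", "LEUTX", "KHDC1L")
HUMAN_REFERENCE_GENES = ("AHSA1", "RPL27")

# Murine DUX4-responsive genes forming the in vivo 4-gene composite, and
# the reference gene for murine tissue RT-qPCR.
MURINE_COMPOSITE_GENES = ("Wfdc3", "Ilvbl", "Slc15a2", "Sord")
MURINE_REFERENCE_GENE = "Ppib"

# Printed analysis thresholds.
FDR_THRESHOLD = 0.05          # significance cutoff for DE calls
LFC_THRESHOLD = 1.0           # |log2FC| cutoff for signature concordance
LOG2CPM_THRESHOLD = -3.0      # low-expression filter (average log2CPM)
PANEL_TPM_THRESHOLD = 35.0    # NanoString panel selection: robust expression
PANEL_LFC_THRESHOLD = 1.5     # NanoString panel selection: strong induction
N_SIMULATED_SIRNAS = 10       # simulated siRNAs defining the background set
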