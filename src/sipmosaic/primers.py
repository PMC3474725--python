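"""Published primer sequences used throughout the analyses.

These are study inputs: the naphthalene-dioxygenase (NDO) typing pairs
(Comamonas-type COM1, Pseudomonas-type PSE1), the *nagFCQED* cloning
pair, and the 16S DGGE pair.  All sequences 5'->3'.
"""

from .seqio import PrimerPair

NAGF1_FOR = "TTCCCAGGAGACAACCCATG"
NAGD_REV = "TGAGGCGACAATGAACATGC"

COM1 = PrimerPair("COM1", "AAAAGAGTTGTACGGCGATG", "ACGGTAGAATCCGCGATAGC")
PSE1 = PrimerPair("PSE1", "AAAAGAGCTGTATGGCGAGT", "CCGATAGAAGCCACGATAACT")
NAGFCQED = PrimerPair("nagFCQED", NAGF1_FOR, NAGD_REV)
DGGE_16S = PrimerPair(
    "16S_338F_530R",
    "CGCCCGCCGCGCCCCCGCCCCGGCCCGCCGCCCCCGCCCACTCCTACGGGAGGCAGC",
    "GTATTACCGCGGCTGCTG",
)

NDO_SCREEN_PAIRS = [COM1, PSE1]
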