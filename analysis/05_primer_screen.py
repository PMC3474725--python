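"""In-silico NDO primer screen and virtual nagFCQED amplification.

Screens pyrosequencing-style reads from a synthetic nag-bearing genome
with the Comamonas-type (COM1) and Pseudomonas-type (PSE1) naphthalene
dioxygenase primer pairs, and sizes the product of the cloning primers
on the synthetic gene-cluster template.
"""

import sys
from pathlib import Path

from sipmosaic import insilico_pcr as pcr
from sipmosaic import primers
from sipmosaic import synthetic_community as synth

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results"

if __name__ == "__main__":
    seed = int(sys.argv[1]) if len(sys.argv) > 1 else 0
    genome, _ = synth.synthetic_ndo_genome(seed=seed)
    reads, _ = synth.simulate_reads([genome], [1.0], 1500, seed=seed + 1)
    results = pcr.screen_readset(reads, primers.NDO_SCREEN_PAIRS, min_hit_reads=5)
    (OUT / "primer_screen.tsv").write_text(pcr.screen_to_tsv(results))
    for r in results:
        print(f"{r.pair_name}: {r.verdict} ({r.hit_reads} supporting reads)")

    template = synth.synthetic_nagfcqed_record(seed=seed)
    amps = pcr.find_amplicons(template, primers.NAGFCQED, max_mismatch=0)
    (OUT / "nagfcqed_amplicons.tsv").write_text(pcr.amplicons_to_tsv(amps))
    for a in amps:
        print(f"NagF1_For/NagD_Rev product on {a.template_id}: {a.length} bp "
              f"at {a.start + 1}..{a.end} (1-based)")
    print(f"tables under {OUT}")
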