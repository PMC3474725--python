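"""Generate the synthetic study inputs: parent operons, a mosaic
recombinant, mixed operon reads, and heavy/light 16S pools.

Writes FASTA/TSV/JSON inputs plus ground-truth files under
results/simulated/ via the `sipmosaic simulate` machinery.
"""

import sys
from pathlib import Path

from click.testing import CliRunner

from sipmosaic.cli import main

OUT = Path(__file__).resolve().parent.parent / "results" / "simulated"

if __name__ == "__main__":
    seed = int(sys.argv[1]) if len(sys.argv) > 1 else 0
    res = CliRunner().invoke(
        main, ["simulate", "--seed", str(seed), "--out-dir", str(OUT)],
        catch_exceptions=False,
    )
    print(res.output.strip())
    print(f"inputs and truth files are under {OUT}")
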