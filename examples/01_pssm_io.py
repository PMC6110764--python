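"""Round-trip a PSSM through the PSI-BLAST ASCII dialect.

Builds a small random evolutionary profile, writes it in the same layout
PSI-BLAST emits with -out_ascii_pssm, reads it back, and checks the score
matrix survives unchanged.
"""

import tempfile
from pathlib import Path

import numpy as np

from rotpssm import PSSM, read_pssm, write_pssm

rng = np.random.default_rng(0)
pssm = PSSM("demo", rng.integers(-10, 13, size=(8, 20)))

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "demo.pssm"
    write_pssm(pssm, path)
    print(path.read_text().splitlines()[3])  # one residue row of the file
    back = read_pssm(path)

print("rows x cols:", back.scores.shape)
print("round-trip identical:", np.array_equal(back.scores, pssm.scores))
# The printed row shows: position, residue, 20 integer log-odds scores
# (the evolutionary signal used downstream), then placeholder percentage
# columns that the parser ignores.
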