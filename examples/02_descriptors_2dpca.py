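"""Turn variable-length profiles into fixed-length 2DPCA descriptors.

Generates a few synthetic proteins, standardises each N x 20 profile to a
20 x 20 Gram matrix, fits the 2DPCA basis, and projects a protein pair
into the concatenated feature vector a classifier consumes.
"""

import numpy as np

from rotpssm import (
    SyntheticConfig,
    TwoDPCAConfig,
    fit_2dpca,
    generate_proteins,
    pair_feature,
    project,
    pssm_to_fixed,
)

config = SyntheticConfig(n_proteins=20, n_pairs_per_class=10,
                         length_range=(40, 120), seed=1)
proteins = generate_proteins(config)

tdp = TwoDPCAConfig(d=5)
fixed = [pssm_to_fixed(p, tdp) for p in proteins.pssms.values()]
basis = fit_2dpca(fixed, d=5, config=tdp)
print("top-5 scatter eigenvalues:", np.round(basis.eigenvalues, 1))

fa = project(fixed[0], basis)
fb = project(fixed[1], basis)
pair = pair_feature(fa, fb, label=1)
print("per-protein descriptor length:", fa.values.size)   # 20 * d
print("pair feature length:", pair.values.size)           # 2 * 20 * d
# Eigenvalues quantify how much profile variation each projection axis
# captures; the pair vector is the classifier input for one candidate
# interaction.
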