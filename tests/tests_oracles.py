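"""Independent brute-force oracles shared across test modules."""

import numpy as np

from raecg.encoding import morlet


def brute_force(x, scales, psi=morlet):
    """O(n_scales * n^2) direct evaluation of the discretised wavelet sum."""
    n = len(x)
    t = np.arange(n)
    out = np.empty((len(scales), n))
    for i, a in enumerate(scales):
        for b in range(n):
            out[i, b] = np.sum(x * psi((t - b) / a)) / np.sqrt(a)
    return np.abs(out)
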