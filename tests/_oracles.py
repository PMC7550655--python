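"""Independent brute-force oracles shared by test modules."""

import numpy as np


def grid_search_rss(signal, b, d_fixed, dstar_max=0.5, n_dstar=200,
                    n_f=101):
    """Best bi-exponential rss over an exhaustive D* × f lattice.

    D is held at ``d_fixed``; for each lattice point the optimal S0 has
    the closed form of a linear scale parameter. Independent of the
    package's optimizer — plain enumeration.
    """
    dstars = np.linspace(d_fixed * (1 + 1e-9), dstar_max, n_dstar)
    fs = np.linspace(0.0, 1.0, n_f)
    slow = np.exp(-b * d_fixed)
    fast = np.exp(-b * dstars[:, None])                  # (n_dstar, nb)
    m = (1 - fs[None, :, None]) * slow + fs[None, :, None] * fast[:, None, :]
    denom = np.sum(m * m, axis=-1)
    s0 = np.where(denom > 0, (m @ signal) / np.where(denom > 0, denom, 1.0),
                  0.0)
    rss = np.sum((s0[..., None] * m - signal) ** 2, axis=-1)
    rss = np.where(s0 > 0, rss, np.inf)
    return float(rss.min())
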