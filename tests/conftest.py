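"""Shared fixtures and independent sampling oracles.

The samplers here deliberately re-derive the displacement densities from
first principles (inverse-transform / rejection sampling on an inline
formula) so that fitting tests check the package against an independent
route, not against itself.
"""

from __future__ import annotations

import numpy as np
import pytest

NM2_PER_MS = 1.0e3  # 1 um^2/s in nm^2/ms


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def sample_rayleigh_truncated(rng, n, D, dt_ms, r_max_nm):
    """Draw step lengths of 2D Brownian motion, truncated at r_max.

    Inverse transform: r = sqrt(s * Exp(1)) with s = 4 D dt; draws beyond
    the cutoff are rejected, which is exactly the truncated density.
    """
    s = 4.0 * D * NM2_PER_MS * dt_ms
    out = np.empty(0)
    while out.size < n:
        cand = np.sqrt(s * rng.exponential(size=2 * n))
        out = np.concatenate([out, cand[cand <= r_max_nm]])
    return out[:n]


def sample_mixture_truncated(rng, n, components, b, dt_ms, r_max_nm):
    """Rejection-sample the truncated multi-component + background density.

    The density formula is written out inline (numerator of the model:
    sum_i f_i (2r/s_i) exp(-r^2/s_i) + b r on [0, r_max]) so this sampler is
    independent of the package's pdf implementation.
    """
    D = np.array([c[0] for c in components])
    f = np.array([c[1] for c in components])
    s = 4.0 * D * NM2_PER_MS * dt_ms

    def dens(r):
        rr = np.atleast_1d(r)[:, None]
        return np.sum(f / s * 2 * rr * np.exp(-rr ** 2 / s), axis=1) + b * rr[:, 0]

    grid = np.linspace(0, r_max_nm, 4001)
    m = 1.05 * dens(grid).max()
    out = np.empty(0)
    while out.size < n:
        cand = rng.uniform(0, r_max_nm, size=4 * n)
        u = rng.uniform(0, m, size=4 * n)
        out = np.concatenate([out, cand[u < dens(cand)]])
    return out[:n]


def make_displacement_set(r, dt_ms, r_max_nm, rng=None):
    """Wrap raw step lengths in a DisplacementSet (steps along +x)."""
    from smdmap.smdm import DisplacementSet

    r = np.asarray(r, float)
    z = np.zeros_like(r)
    return DisplacementSet(z, z, r, z, np.zeros(r.size, int),
                           dt_ms=dt_ms, r_max_nm=r_max_nm)
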