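"""Numba kernels for the single-site Gibbs sweeps.

All random draws are pre-generated by the caller from one numpy Generator, so
chains are bit-reproducible for a fixed seed regardless of numba internals.
Each kernel updates one effect block over a marker range, maintaining the
residual incrementally.

Conventions: ``XT`` is the (p, n) transposed marker matrix with samples sorted
by group; ``gs`` holds group row offsets; a block touching only group k passes
``kfrom = k-1, kto = k`` while the main block passes ``kfrom = 0, kto = q``.
``winv[k] = 1 / sigma2_k`` are the residual precisions and ``xtx[k, j]`` the
per-group squared column norms.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["sweep_brr", "sweep_bayesb", "spike_logodds"]


@njit(cache=False)
def spike_logodds(c0: float, rhs0: float, v: float) -> float:
    """Log marginal-likelihood ratio for including one marker.

    With the effect integrated out under b ~ N(0, v), the Bayes factor of the
    slab against the point mass is
    ``(1 + v c0)^{-1/2} exp(v rhs0^2 / (2 (1 + v c0)))`` where ``c0`` is the
    precision-weighted squared column norm and ``rhs0`` the precision-weighted
    inner product of the marker with the full residual (effect removed).
    """
    t = 1.0 + v * c0
    return -0.5 * np.log(t) + 0.5 * v * rhs0 * rhs0 / t


@njit(cache=False)
def sweep_brr(XT, xtx, e, gs, kfrom, kto, winv, beta, prior_prec, z, j0, j1):
    """Gaussian single-site updates for markers ``j0..j1-1`` of one block.

    The full-conditional precision is ``sum_k xtx[k,j] / sigma2_k +
    prior_prec``; for a group block only that group's rows contribute.
    ``z`` supplies one standard-normal draw per marker (indexed by j).
    """
    for j in range(j0, j1):
        xj = XT[j]
        b = beta[j]
        c = prior_prec
        rhs = 0.0
        for k in range(kfrom, kto):
            s = 0.0
            for i in range(gs[k], gs[k + 1]):
                s += xj[i] * e[i]
            w = winv[k]
            rhs += (s + xtx[k, j] * b) * w
            c += xtx[k, j] * w
        bn = rhs / c + z[j] / np.sqrt(c)
        d = bn - b
        beta[j] = bn
        if d != 0.0:
            for k in range(kfrom, kto):
                for i in range(gs[k], gs[k + 1]):
                    e[i] -= xj[i] * d


@njit(cache=False)
def sweep_bayesb(
    XT, xtx, e, gs, kfrom, kto, winv,
    beta, delta, s2j, S, df, logit_pi,
    z, u, chi_in, chi_out, j0, j1,
):
    """Spike-slab single-site updates for markers ``j0..j1-1`` of one block.

    Per marker: (a) draw the inclusion indicator from its Bernoulli
    conditional with the effect integrated out given the current per-marker
    variance; (b) if included, draw the effect from its Gaussian conditional,
    else set it to zero; (c) refresh the per-marker variance from its
    scaled-inverse-chi-square conditional (df+1 degrees of freedom when the
    marker is in the model).  ``u`` are Uniform(0,1) draws, ``chi_in`` /
    ``chi_out`` chi-square draws with df+1 / df degrees of freedom.
    """
    for j in range(j0, j1):
        xj = XT[j]
        b = beta[j]
        c0 = 0.0
        rhs = 0.0
        for k in range(kfrom, kto):
            s = 0.0
            for i in range(gs[k], gs[k + 1]):
                s += xj[i] * e[i]
            w = winv[k]
            rhs += (s + xtx[k, j] * b) * w
            c0 += xtx[k, j] * w
        v = s2j[j]
        if v < 1e-12:
            v = 1e-12
        lo = logit_pi + spike_logodds(c0, rhs, v)
        p1 = 1.0 / (1.0 + np.exp(-lo))
        if u[j] < p1:
            cc = c0 + 1.0 / v
            bn = rhs / cc + z[j] / np.sqrt(cc)
            delta[j] = 1
            s2j[j] = (S * df + bn * bn) / chi_in[j]
        else:
            bn = 0.0
            delta[j] = 0
            s2j[j] = S * df / chi_out[j]
        d = bn - b
        beta[j] = bn
        if d != 0.0:
            for k in range(kfrom, kto):
                for i in range(gs[k], gs[k + 1]):
                    e[i] -= xj[i] * d
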