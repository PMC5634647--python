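"""Compiled trial-loop likelihood for hybrid two-system agents.

The hierarchical fit evaluates the choice likelihood tens of thousands of
times, so the sequential trial loop is JIT-compiled.  The semantics mirror
the reference agents in :mod:`contingencyrl.agents` exactly (this is
enforced by tests that replay fixtures through both paths): each of the two
value systems is either a model-free TD(lam) learner or a model-based
planner, their first-level action values are mixed with a per-trial weight,
and only first-level trials with a recorded choice contribute likelihood
terms, while every trial's observed transition and reward update the
systems.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

KIND_MF = 0
KIND_MB = 1


@njit(cache=True)
def nll_core(start, choice, s2, ter, reward, widx, wvec,
             kind_hi, alpha_hi, lam_hi, atrans_hi,
             kind_lo, alpha_lo, lam_lo, atrans_lo,
             beta, stay_bias, fictive):
    """Negative log-likelihood of the observed first-level choices.

    Parameters are natural-scale scalars; ``wvec`` holds the mixture
    weight components and ``widx`` selects the component per trial.
    ``choice`` is -1 where no first-level choice was made.
    """
    n = start.shape[0]
    # system state (both banks allocated; kind selects which fields are used)
    q0_hi = np.full(2, 0.5)
    q2_hi = np.full(2, 0.5)
    p_hi = 1.0
    r_hi = np.full(2, 0.5)
    q0_lo = np.full(2, 0.5)
    q2_lo = np.full(2, 0.5)
    p_lo = 1.0
    r_lo = np.full(2, 0.5)
    prev = -1
    nll = 0.0
    for t in range(n):
        c = choice[t]
        if start[t] == 0 and c >= 0:
            # first-level action values of each system
            if kind_hi == KIND_MB:
                qh0 = p_hi * r_hi[0] + (1.0 - p_hi) * r_hi[1]
                qh1 = (1.0 - p_hi) * r_hi[0] + p_hi * r_hi[1]
            else:
                qh0 = q0_hi[0]
                qh1 = q0_hi[1]
            if kind_lo == KIND_MB:
                ql0 = p_lo * r_lo[0] + (1.0 - p_lo) * r_lo[1]
                ql1 = (1.0 - p_lo) * r_lo[0] + p_lo * r_lo[1]
            else:
                ql0 = q0_lo[0]
                ql1 = q0_lo[1]
            w = wvec[widx[t]]
            qa = w * qh0 + (1.0 - w) * ql0
            qb = w * qh1 + (1.0 - w) * ql1
            if prev == 0:
                qa += stay_bias
            elif prev == 1:
                qb += stay_bias
            za = beta * qa
            zb = beta * qb
            m = za if za > zb else zb
            lse = m + math.log(math.exp(za - m) + math.exp(zb - m))
            if c == 0:
                nll -= za - lse
            else:
                nll -= zb - lse
            prev = c
        # learning updates (every trial, including second-level starts)
        s = s2[t]
        e = ter[t]
        r = reward[t]
        took_choice = start[t] == 0 and c >= 0
        # high system
        if kind_hi == KIND_MB:
            obs_a = 1.0 if e == s else 0.0
            p_hi += atrans_hi * (obs_a - p_hi)
            r_hi[e] += alpha_hi * (r - r_hi[e])
            if fictive:
                r_hi[1 - e] = 1.0 - r_hi[e]
        else:
            d2 = r - q2_hi[s]
            if took_choice:
                d1 = q2_hi[s] - q0_hi[c]
                q0_hi[c] += alpha_hi * d1 + alpha_hi * lam_hi * d2
            q2_hi[s] += alpha_hi * d2
            if fictive:
                q2_hi[1 - s] = 1.0 - q2_hi[s]
        # low system
        if kind_lo == KIND_MB:
            obs_a = 1.0 if e == s else 0.0
            p_lo += atrans_lo * (obs_a - p_lo)
            r_lo[e] += alpha_lo * (r - r_lo[e])
            if fictive:
                r_lo[1 - e] = 1.0 - r_lo[e]
        else:
            d2 = r - q2_lo[s]
            if took_choice:
                d1 = q2_lo[s] - q0_lo[c]
                q0_lo[c] += alpha_lo * d1 + alpha_lo * lam_lo * d2
            q2_lo[s] += alpha_lo * d2
            if fictive:
                q2_lo[1 - s] = 1.0 - q2_lo[s]
    return nll
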