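"""Compiled random-walk Metropolis kernels.

Each kernel samples the posterior of one model for one SNP's count summary.
Proposals are Gaussian steps; a proposal outside the constrained parametric
space has prior density zero and is rejected. The genotypic kernel targets
likelihood times the (unnormalised) conditional-flat prior shape; the allelic
priors are flat so only the likelihood enters.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=True)
def _ll_overall(a, kA, kB, m):
    p = 0.5 + a
    q = 0.5 - a
    ll = 0.0
    if kA > 0:
        if p <= 0.0:
            return -np.inf
        ll += kA * math.log(p)
    if kB > 0:
        if q <= 0.0:
            return -np.inf
        ll += kB * math.log(q)
    if m > 0:
        pab = 2.0 * p * q
        if pab <= 0.0:
            return -np.inf
        ll += m * math.log(pab)
    return ll


@njit(cache=True)
def run_allelic_overall(kA, kB, m, n_iter, n_burn, thin, prop_sd, seed):
    np.random.seed(seed)
    n_keep = (n_iter - n_burn + thin - 1) // thin
    out = np.empty(n_keep)
    a = 0.0
    ll = _ll_overall(a, kA, kB, m)
    k = 0
    for it in range(n_iter):
        prop = a + np.random.normal() * prop_sd
        if -0.5 <= prop <= 0.5:
            llp = _ll_overall(prop, kA, kB, m)
            if llp - ll > math.log(np.random.random()):
                a = prop
                ll = llp
        if it >= n_burn and (it - n_burn) % thin == 0:
            out[k] = a
            k += 1
    return out


@njit(cache=True)
def _ll_parent_specific(a_s, a_d, ksA, ksB, kdA, kdB, m):
    ps = 0.5 + a_s
    pd = 0.5 + a_d
    ll = 0.0
    if ksA > 0:
        if ps <= 0.0:
            return -np.inf
        ll += ksA * math.log(ps)
    if ksB > 0:
        if 1.0 - ps <= 0.0:
            return -np.inf
        ll += ksB * math.log(1.0 - ps)
    if kdA > 0:
        if pd <= 0.0:
            return -np.inf
        ll += kdA * math.log(pd)
    if kdB > 0:
        if 1.0 - pd <= 0.0:
            return -np.inf
        ll += kdB * math.log(1.0 - pd)
    if m > 0:
        pab = ps * (1.0 - pd) + (1.0 - ps) * pd
        if pab <= 0.0:
            return -np.inf
        ll += m * math.log(pab)
    return ll


@njit(cache=True)
def run_parent_specific(ksA, ksB, kdA, kdB, m, n_iter, n_burn, thin, prop_sd, seed):
    np.random.seed(seed)
    n_keep = (n_iter - n_burn + thin - 1) // thin
    out = np.empty((n_keep, 2))
    a_s = 0.0
    a_d = 0.0
    ll = _ll_parent_specific(a_s, a_d, ksA, ksB, kdA, kdB, m)
    k = 0
    for it in range(n_iter):
        ps_prop = a_s + np.random.normal() * prop_sd
        pd_prop = a_d + np.random.normal() * prop_sd
        if -0.5 <= ps_prop <= 0.5 and -0.5 <= pd_prop <= 0.5:
            llp = _ll_parent_specific(ps_prop, pd_prop, ksA, ksB, kdA, kdB, m)
            if llp - ll > math.log(np.random.random()):
                a_s = ps_prop
                a_d = pd_prop
                ll = llp
        if it >= n_burn and (it - n_burn) % thin == 0:
            out[k, 0] = a_s
            out[k, 1] = a_d
            k += 1
    return out


@njit(cache=True)
def _geno_in_space(ag, dg):
    if ag < -1.0 or ag > 1.0:
        return False
    if dg < -1.0 or dg > abs(ag):
        return False
    if dg > 0.0 and abs(ag) > 1.0 - dg:
        return False
    return True


@njit(cache=True)
def _ll_genotypic(ag, dg, nAA, nAB, nBB, cAA, cAB, cAB2, cBB2):
    ll = 0.0
    pAA = (1.0 + ag - dg) / 4.0
    pAB = (1.0 + dg) / 2.0
    pBB = (1.0 - ag - dg) / 4.0
    zA = 2.0 * (1.0 + ag / 2.0)
    zB = 2.0 * (1.0 - ag / 2.0)
    if nAA > 0:
        if pAA <= 0.0:
            return -np.inf
        ll += nAA * math.log(pAA)
    if nAB > 0:
        if pAB <= 0.0:
            return -np.inf
        ll += nAB * math.log(pAB)
    if nBB > 0:
        if pBB <= 0.0:
            return -np.inf
        ll += nBB * math.log(pBB)
    if cAA > 0:
        v = (1.0 + ag - dg) / zA
        if v <= 0.0:
            return -np.inf
        ll += cAA * math.log(v)
    if cAB > 0:
        v = (1.0 + dg) / zA
        if v <= 0.0:
            return -np.inf
        ll += cAB * math.log(v)
    if cAB2 > 0:
        v = (1.0 + dg) / zB
        if v <= 0.0:
            return -np.inf
        ll += cAB2 * math.log(v)
    if cBB2 > 0:
        v = (1.0 - ag - dg) / zB
        if v <= 0.0:
            return -np.inf
        ll += cBB2 * math.log(v)
    return ll


@njit(cache=True)
def _log_prior_genotypic(ag, dg):
    if dg > 0.0:
        lp = math.log(2.0 / (2.0 - 2.0 * dg))
    else:
        lp = math.log(0.5)
    return lp - math.log(1.0 + abs(ag))


@njit(cache=True)
def run_genotypic(nAA, nAB, nBB, cAA, cAB, cAB2, cBB2, n_iter, n_burn, thin, prop_sd, seed):
    np.random.seed(seed)
    n_keep = (n_iter - n_burn + thin - 1) // thin
    out = np.empty((n_keep, 2))
    ag = 0.0
    dg = 0.0
    post = _ll_genotypic(ag, dg, nAA, nAB, nBB, cAA, cAB, cAB2, cBB2) + _log_prior_genotypic(ag, dg)
    k = 0
    for it in range(n_iter):
        ag_prop = ag + np.random.normal() * prop_sd
        dg_prop = dg + np.random.normal() * prop_sd
        if _geno_in_space(ag_prop, dg_prop):
            pp = _ll_genotypic(ag_prop, dg_prop, nAA, nAB, nBB, cAA, cAB, cAB2, cBB2) + _log_prior_genotypic(
                ag_prop, dg_prop
            )
            if pp - post > math.log(np.random.random()):
                ag = ag_prop
                dg = dg_prop
                post = pp
        if it >= n_burn and (it - n_burn) % thin == 0:
            out[k, 0] = ag
            out[k, 1] = dg
            k += 1
    return out
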