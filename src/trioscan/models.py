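"""Allelic and genotypic transmission-ratio-distortion parameterisations.

Three nested views of distorted transmission at a biallelic SNP:

* **overall allelic** -- one parameter ``alpha``: a heterozygous parent
  transmits allele A with probability ``0.5 + alpha``, ``alpha`` in
  ``[-0.5, 0.5]`` with a flat prior.
* **parent-specific allelic** -- ``alpha_s`` (sire/stallion) and ``alpha_d``
  (dam/mare), each as above.
* **genotypic** -- additive ``alpha_g`` and dominance ``delta_g`` effects on
  offspring genotype frequencies, regardless of parental origin. For a
  het x het mating the offspring probabilities are
  ``((1+a-d)/4, (1+d)/2, (1-a-d)/4)``; for het x hom matings the surviving
  two genotype classes are renormalised so the probabilities sum to one.
  The parametric space couples the two parameters: ``delta_g`` in
  ``[-1, |alpha_g|]`` and, when ``delta_g > 0``, ``alpha_g`` restricted to
  ``[-1+delta_g, 1-delta_g]``.

All log-likelihoods are computed over the same observation space -- the
offspring genotypes of informative (het x het and het x hom) matings -- so
that deviance-based comparisons between the parameterisations are meaningful.
For the allelic models this means the unresolvable AB offspring of het x het
matings enter through their marginal probability
``p_s(1-p_d) + (1-p_s)p_d`` (``2p(1-p)`` in the overall model); with no such
offspring the likelihood reduces exactly to the familiar binomial over
resolved transmission counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import xlogy

from .transmission import TransmissionSummary

MODEL_TAGS = ("allelic_overall", "allelic_parent_specific", "genotypic")


class DomainError(ValueError):
    """Parameters outside the model's parametric space."""


@dataclass(frozen=True)
class AllelicParams:
    alpha: float

    def in_space(self) -> bool:
        return -0.5 <= self.alpha <= 0.5


@dataclass(frozen=True)
class ParentSpecificParams:
    alpha_s: float
    alpha_d: float

    def in_space(self) -> bool:
        return -0.5 <= self.alpha_s <= 0.5 and -0.5 <= self.alpha_d <= 0.5


@dataclass(frozen=True)
class GenotypicParams:
    alpha_g: float
    delta_g: float

    def in_space(self) -> bool:
        return genotypic_in_space(self.alpha_g, self.delta_g)


def genotypic_in_space(alpha_g: float, delta_g: float) -> bool:
    """Prior support: validity plus the coupled bound ``delta_g <= |alpha_g|``."""
    if not genotypic_valid(alpha_g, delta_g):
        return False
    return delta_g <= abs(alpha_g)


def genotypic_valid(alpha_g: float, delta_g: float) -> bool:
    """Probability-validity region: all offspring probabilities in [0, 1].

    This is the widest region on which the genotypic formulas define a
    probability simplex (``|alpha_g| <= 1`` and ``-1 <= delta_g <= 1 -
    |alpha_g|``); the prior support used for inference is the tighter
    coupled space of :func:`genotypic_in_space`.
    """
    if not -1.0 <= alpha_g <= 1.0:
        return False
    return -1.0 <= delta_g <= 1.0 - abs(alpha_g) + 1e-15


def allelic_transmission_prob(p: AllelicParams) -> tuple[float, float]:
    """``(P(A), P(B))`` transmitted by a heterozygous parent."""
    if not p.in_space():
        raise DomainError(f"alpha={p.alpha} outside [-0.5, 0.5]")
    return 0.5 + p.alpha, 0.5 - p.alpha


def genotypic_offspring_probs(mating: str, p: GenotypicParams) -> tuple[float, float, float]:
    """Offspring genotype probabilities ``(P(AA), P(AB), P(BB))`` for a mating type.

    ``mating`` is ``"hetxhet"``, ``"homAAxhet"`` or ``"homBBxhet"``. The
    hom-BB case is the exact mirror of the hom-AA case (allele labels swapped,
    ``alpha_g`` negated for the surviving classes).
    """
    if not genotypic_valid(p.alpha_g, p.delta_g):
        raise DomainError(f"(alpha_g={p.alpha_g}, delta_g={p.delta_g}) outside the valid region")
    a, d = p.alpha_g, p.delta_g
    if mating == "hetxhet":
        return (1 + a - d) / 4.0, (1 + d) / 2.0, (1 - a - d) / 4.0
    if mating == "homAAxhet":
        z = 2.0 * (1.0 + a / 2.0)
        return (1 + a - d) / z, (1 + d) / z, 0.0
    if mating == "homBBxhet":
        z = 2.0 * (1.0 - a / 2.0)
        return 0.0, (1 + d) / z, (1 - a - d) / z
    raise ValueError(f"unknown mating type {mating!r}")


def _xlogy_sum(counts, probs) -> float:
    """Sum of k*log(p) terms; -inf when a zero-probability class has count."""
    total = 0.0
    for k, pr in zip(counts, probs):
        if k == 0:
            continue
        if pr <= 0.0:
            return -np.inf
        total += k * np.log(pr)
    return total


def allelic_loglik(s: TransmissionSummary, p, mode: str | None = None) -> float:
    """Log-likelihood of a transmission summary under an allelic model.

    Accepts :class:`AllelicParams` (overall) or :class:`ParentSpecificParams`;
    ``mode`` may be given explicitly as ``"overall"``/``"parent_specific"``.
    """
    if mode is None:
        mode = "overall" if isinstance(p, AllelicParams) else "parent_specific"
    if mode == "overall":
        if isinstance(p, ParentSpecificParams):
            raise ValueError("overall mode requires AllelicParams")
        pa, _ = allelic_transmission_prob(p)
        ps = pd_ = pa
    elif mode == "parent_specific":
        if not p.in_space():
            raise DomainError(f"{p} outside [-0.5, 0.5]^2")
        ps, pd_ = 0.5 + p.alpha_s, 0.5 + p.alpha_d
    else:
        raise ValueError(f"unknown mode {mode!r}")
    ll = _xlogy_sum(s.sire_counts, (ps, 1 - ps))
    ll += _xlogy_sum(s.dam_counts, (pd_, 1 - pd_))
    m = s.n_hethet_ab
    if m:
        p_ab = ps * (1 - pd_) + (1 - ps) * pd_
        if p_ab <= 0.0:
            return -np.inf
        ll += m * np.log(p_ab)
    return float(ll)


def genotypic_loglik(s: TransmissionSummary, p: GenotypicParams) -> float:
    """Log-likelihood of offspring genotype cells under the genotypic model."""
    if not genotypic_valid(p.alpha_g, p.delta_g):
        raise DomainError(f"(alpha_g={p.alpha_g}, delta_g={p.delta_g}) outside the valid region")
    ll = _xlogy_sum(s.hethet_cells, genotypic_offspring_probs("hetxhet", p))
    paa = genotypic_offspring_probs("homAAxhet", p)
    ll += _xlogy_sum(s.hethom_aa_cells, (paa[0], paa[1]))
    pbb = genotypic_offspring_probs("homBBxhet", p)
    ll += _xlogy_sum(s.hethom_bb_cells, (pbb[1], pbb[2]))
    return float(ll)


def prior_density(p) -> float:
    """Prior density at ``p`` (zero outside the parametric space).

    Allelic priors are flat (density 1 over the unit-length interval, or the
    unit square for the parent-specific pair). The genotypic prior is the
    product of the two conditional flat densities over the coupled space:
    ``p(alpha_g) = 1/2`` for ``delta_g <= 0`` and ``2/(2 - 2 delta_g)``
    otherwise, times ``p(delta_g) = 1/(1 + |alpha_g|)``; the product is
    renormalised numerically wherever a proper prior is required.
    """
    if isinstance(p, AllelicParams):
        return 1.0 if p.in_space() else 0.0
    if isinstance(p, ParentSpecificParams):
        return 1.0 if p.in_space() else 0.0
    if isinstance(p, GenotypicParams):
        if not p.in_space():
            return 0.0
        p_ag = 2.0 / (2.0 - 2.0 * p.delta_g) if p.delta_g > 0 else 0.5
        p_dg = 1.0 / (1.0 + abs(p.alpha_g))
        return p_ag * p_dg
    raise TypeError(f"unsupported parameter type {type(p).__name__}")


def _genotypic_prior_shape(ag: np.ndarray, dg: np.ndarray) -> np.ndarray:
    p_ag = np.where(dg > 0, 2.0 / (2.0 - 2.0 * dg), 0.5)
    return p_ag / (1.0 + np.abs(ag))


@lru_cache(maxsize=4)
def genotypic_grid(n_ag: int = 201, n_dg: int = 201):
    """Midpoint quadrature grid over the coupled (alpha_g, delta_g) space.

    Returns flattened arrays ``(ag, dg, weight, prior)`` where ``weight`` is
    the cell area and ``prior`` the (unnormalised) prior shape; the prior
    normalising constant is ``sum(weight * prior)``.
    """
    da = 2.0 / n_ag
    ag_nodes = -1.0 + (np.arange(n_ag) + 0.5) * da
    ags, dgs, ws = [], [], []
    for a in ag_nodes:
        d_hi = min(abs(a), 1.0 - abs(a))
        length = d_hi + 1.0
        dd = length / n_dg
        d_nodes = -1.0 + (np.arange(n_dg) + 0.5) * dd
        ags.append(np.full(n_dg, a))
        dgs.append(d_nodes)
        ws.append(np.full(n_dg, da * dd))
    ag = np.concatenate(ags)
    dg = np.concatenate(dgs)
    w = np.concatenate(ws)
    prior = _genotypic_prior_shape(ag, dg)
    return ag, dg, w, prior


# ---------------------------------------------------------------------------
# vectorised log-likelihoods (used by the quadrature Bayes factors and DIC)

def allelic_overall_loglik_vec(s: TransmissionSummary, alpha: np.ndarray) -> np.ndarray:
    kA = s.sire_counts[0] + s.dam_counts[0]
    kB = s.sire_counts[1] + s.dam_counts[1]
    m = s.n_hethet_ab
    p = 0.5 + np.asarray(alpha, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = xlogy(kA, p) + xlogy(kB, 1 - p) + xlogy(m, 2 * p * (1 - p))
    return np.where(np.isnan(ll), -np.inf, ll)


def parent_specific_loglik_vec(s: TransmissionSummary, alpha_s: np.ndarray, alpha_d: np.ndarray) -> np.ndarray:
    ps = 0.5 + np.asarray(alpha_s, dtype=float)
    pd_ = 0.5 + np.asarray(alpha_d, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = (
            xlogy(s.sire_counts[0], ps)
            + xlogy(s.sire_counts[1], 1 - ps)
            + xlogy(s.dam_counts[0], pd_)
            + xlogy(s.dam_counts[1], 1 - pd_)
            + xlogy(s.n_hethet_ab, ps * (1 - pd_) + (1 - ps) * pd_)
        )
    return np.where(np.isnan(ll), -np.inf, ll)


def genotypic_loglik_vec(s: TransmissionSummary, ag: np.ndarray, dg: np.ndarray) -> np.ndarray:
    ag = np.asarray(ag, dtype=float)
    dg = np.asarray(dg, dtype=float)
    nAA, nAB, nBB = s.hethet_cells
    cAA, cAB = s.hethom_aa_cells
    cAB2, cBB2 = s.hethom_bb_cells
    zA = 2.0 * (1.0 + ag / 2.0)
    zB = 2.0 * (1.0 - ag / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = (
            xlogy(nAA, (1 + ag - dg) / 4.0)
            + xlogy(nAB, (1 + dg) / 2.0)
            + xlogy(nBB, (1 - ag - dg) / 4.0)
            + xlogy(cAA, (1 + ag - dg) / zA)
            + xlogy(cAB, (1 + dg) / zA)
            + xlogy(cAB2, (1 + dg) / zB)
            + xlogy(cBB2, (1 - ag - dg) / zB)
        )
    return np.where(np.isnan(ll), -np.inf, ll)


def loglik(s: TransmissionSummary, model_tag: str, theta: np.ndarray) -> np.ndarray:
    """Dispatch log-likelihood for ``theta`` (scalar row or array of draws)."""
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    if model_tag == "allelic_overall":
        return allelic_overall_loglik_vec(s, theta[:, 0])
    if model_tag == "allelic_parent_specific":
        return parent_specific_loglik_vec(s, theta[:, 0], theta[:, 1])
    if model_tag == "genotypic":
        return genotypic_loglik_vec(s, theta[:, 0], theta[:, 1])
    raise ValueError(f"unknown model_tag {model_tag!r}")


def null_loglik(s: TransmissionSummary, model_tag: str) -> float:
    """Log-likelihood at the Mendelian null (all distortion parameters zero)."""
    dim = 1 if model_tag == "allelic_overall" else 2
    return float(loglik(s, model_tag, np.zeros((1, dim)))[0])


def in_space(model_tag: str, theta: np.ndarray) -> bool:
    theta = np.asarray(theta, dtype=float)
    if model_tag == "allelic_overall":
        return bool(-0.5 <= theta[0] <= 0.5)
    if model_tag == "allelic_parent_specific":
        return bool(np.all((-0.5 <= theta) & (theta <= 0.5)))
    if model_tag == "genotypic":
        return genotypic_in_space(float(theta[0]), float(theta[1]))
    raise ValueError(f"unknown model_tag {model_tag!r}")
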