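"""Posterior sampling, Bayes factors, DIC, and inheritance-pattern calls.

Significance of distortion at a SNP is a Bayes factor: the prior-integrated
marginal likelihood of the distortion model divided by the likelihood of the
Mendelian null (all distortion parameters zero). The overall allelic marginal
has a closed Beta-function form; the parent-specific and genotypic marginals
are computed by deterministic midpoint quadrature over their prior spaces.
Goodness of fit across parameterisations is compared with the deviance
information criterion computed from the retained posterior draws.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import betaln, logsumexp

from . import models
from ._kernels import run_allelic_overall, run_genotypic, run_parent_specific
from .transmission import TransmissionSummary

logger = logging.getLogger(__name__)

LOG10_DECISIVE = 2.0  # Jeffreys "decisive": BF > 100

_PARAM_NAMES = {
    "allelic_overall": ("alpha",),
    "allelic_parent_specific": ("alpha_s", "alpha_d"),
    "genotypic": ("alpha_g", "delta_g"),
}

# simplicity order used for tie-breaking between models within the DIC margin
_SIMPLICITY = ("allelic_overall", "allelic_parent_specific", "genotypic")


@dataclass
class McmcConfig:
    """Random-walk Metropolis settings. Defaults follow the study profile
    (110,000 iterations, 10,000 burn-in); :meth:`desk` is a 10x-reduced
    profile for interactive work and testing."""

    n_iter: int = 110_000
    n_burnin: int = 10_000
    seed: int = 0
    proposal_sd: float = 0.05
    thin: int = 1

    def __post_init__(self) -> None:
        if self.n_burnin >= self.n_iter:
            raise ValueError("n_burnin must be < n_iter")
        if self.proposal_sd <= 0:
            raise ValueError("proposal_sd must be > 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @classmethod
    def study(cls, seed: int = 0, thin: int = 1) -> "McmcConfig":
        return cls(n_iter=110_000, n_burnin=10_000, seed=seed, thin=thin)

    @classmethod
    def desk(cls, seed: int = 0, thin: int = 1) -> "McmcConfig":
        return cls(n_iter=11_000, n_burnin=1_000, seed=seed, thin=thin)


def batch_means_ess(x: np.ndarray, n_batches: int = 50) -> float:
    """Effective sample size via the batch-means variance ratio."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2 * n_batches:
        return float(n)
    v = x.var()
    if v == 0.0:
        return float(n)
    bsize = n // n_batches
    means = x[: bsize * n_batches].reshape(n_batches, bsize).mean(axis=1)
    v_bm = means.var()
    if v_bm == 0.0:
        return float(n)
    tau = bsize * v_bm / v
    return float(min(n, max(1.0, n / tau)))


@dataclass
class PosteriorSummary:
    """Per-parameter posterior moments, central 95% interval, and ESS."""

    params: tuple[str, ...]
    mean: np.ndarray
    median: np.ndarray
    sd: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    ess: np.ndarray
    draws: np.ndarray | None = None

    @property
    def n_draws(self) -> int:
        return 0 if self.draws is None else self.draws.shape[0]

    def mc_se(self) -> np.ndarray:
        return self.sd / np.sqrt(np.maximum(self.ess, 1.0))

    def ci_excludes_zero(self, param: str) -> bool:
        i = self.params.index(param)
        return bool(self.ci_low[i] > 0.0 or self.ci_high[i] < 0.0)

    def __getitem__(self, param: str) -> dict[str, float]:
        i = self.params.index(param)
        return {
            "mean": float(self.mean[i]),
            "median": float(self.median[i]),
            "sd": float(self.sd[i]),
            "ci_low": float(self.ci_low[i]),
            "ci_high": float(self.ci_high[i]),
            "ess": float(self.ess[i]),
        }


@dataclass
class InferenceResult:
    model_tag: str
    posterior: PosteriorSummary
    log10_bf: float
    dic: float


def _summarize_draws(draws: np.ndarray, names: tuple[str, ...], keep_draws: bool) -> PosteriorSummary:
    draws = np.atleast_2d(draws)
    if draws.shape[1] != len(names):
        draws = draws.reshape(-1, len(names))
    lo, hi = np.percentile(draws, [2.5, 97.5], axis=0)
    return PosteriorSummary(
        params=names,
        mean=draws.mean(axis=0),
        median=np.median(draws, axis=0),
        sd=draws.std(axis=0, ddof=1) if draws.shape[0] > 1 else np.zeros(draws.shape[1]),
        ci_low=lo,
        ci_high=hi,
        ess=np.array([batch_means_ess(draws[:, j]) for j in range(draws.shape[1])]),
        draws=draws if keep_draws else None,
    )


def run_mcmc(
    s: TransmissionSummary,
    model_tag: str,
    cfg: McmcConfig | None = None,
    keep_draws: bool = True,
) -> PosteriorSummary:
    """Sample the posterior of one model for one SNP's summary."""
    cfg = cfg or McmcConfig()
    if not s.has_data():
        raise ValueError(f"{s.snp_id}: no informative data")
    seed = int(cfg.seed) % (2**31)
    args = (cfg.n_iter, cfg.n_burnin, cfg.thin, cfg.proposal_sd, seed)
    if model_tag == "allelic_overall":
        kA = s.sire_counts[0] + s.dam_counts[0]
        kB = s.sire_counts[1] + s.dam_counts[1]
        draws = run_allelic_overall(float(kA), float(kB), float(s.n_hethet_ab), *args)
        draws = draws.reshape(-1, 1)
    elif model_tag == "allelic_parent_specific":
        draws = run_parent_specific(
            float(s.sire_counts[0]),
            float(s.sire_counts[1]),
            float(s.dam_counts[0]),
            float(s.dam_counts[1]),
            float(s.n_hethet_ab),
            *args,
        )
    elif model_tag == "genotypic":
        draws = run_genotypic(
            float(s.hethet_cells[0]),
            float(s.hethet_cells[1]),
            float(s.hethet_cells[2]),
            float(s.hethom_aa_cells[0]),
            float(s.hethom_aa_cells[1]),
            float(s.hethom_bb_cells[0]),
            float(s.hethom_bb_cells[1]),
            *args,
        )
    else:
        raise ValueError(f"unknown model_tag {model_tag!r}")
    return _summarize_draws(draws, _PARAM_NAMES[model_tag], keep_draws)


def _log10_bf_binomial(kA: int, kB: int, m: int) -> float:
    """Closed-form overall-allelic Bayes factor on the log10 scale.

    Flat prior on alpha over [-0.5, 0.5] is a uniform prior on the
    transmission probability p over [0, 1]; the marginal of
    p^kA (1-p)^kB (2p(1-p))^m is 2^m B(kA+m+1, kB+m+1). With m = 0 this is
    the textbook (1/(n+1)) / (C(n,k) 0.5^n) identity.
    """
    log_marg = m * math.log(2.0) + betaln(kA + m + 1, kB + m + 1)
    log_null = (kA + kB + m) * math.log(0.5)
    return float((log_marg - log_null) / math.log(10.0))


def _grid_1d(n: int = 401) -> tuple[np.ndarray, float]:
    step = 1.0 / n
    return -0.5 + (np.arange(n) + 0.5) * step, step


def bayes_factor(s: TransmissionSummary, model_tag: str, grid_size: int = 201) -> float:
    """log10 Bayes factor of a distortion model against the Mendelian null."""
    ll0 = models.null_loglik(s, model_tag)
    if model_tag == "allelic_overall":
        kA = s.sire_counts[0] + s.dam_counts[0]
        kB = s.sire_counts[1] + s.dam_counts[1]
        return _log10_bf_binomial(kA, kB, s.n_hethet_ab)
    if model_tag == "allelic_parent_specific":
        if s.n_hethet_ab == 0:
            # product of independent per-parent closed forms
            return _log10_bf_binomial(*s.sire_counts, 0) + _log10_bf_binomial(*s.dam_counts, 0)
        nodes, step = _grid_1d(grid_size)
        a_s, a_d = np.meshgrid(nodes, nodes, indexing="ij")
        ll = models.parent_specific_loglik_vec(s, a_s.ravel(), a_d.ravel())
        log_marg = logsumexp(ll - ll0) + 2.0 * math.log(step)
        return float(log_marg / math.log(10.0))
    if model_tag == "genotypic":
        ag, dg, w, prior = models.genotypic_grid(grid_size, grid_size)
        ll = models.genotypic_loglik_vec(s, ag, dg)
        wp = w * prior
        log_z = math.log(wp.sum())
        log_marg = logsumexp(ll - ll0, b=wp) - log_z
        return float(log_marg / math.log(10.0))
    raise ValueError(f"unknown model_tag {model_tag!r}")


def bayes_factor_quadrature(s: TransmissionSummary, model_tag: str = "allelic_overall", n: int = 20001) -> float:
    """Independent 1-D quadrature of the overall-allelic marginal (oracle path)."""
    if model_tag != "allelic_overall":
        raise ValueError("quadrature oracle implemented for the overall allelic model")
    nodes, step = _grid_1d(n)
    ll = models.allelic_overall_loglik_vec(s, nodes)
    ll0 = models.null_loglik(s, model_tag)
    return float((logsumexp(ll - ll0) + math.log(step)) / math.log(10.0))


def compute_dic(s: TransmissionSummary, draws: np.ndarray, model_tag: str) -> float:
    """DIC = mean deviance + effective parameter count p_D.

    ``p_D = mean(D) - D(posterior mean)``; if the posterior mean falls outside
    the constrained space (possible near its boundaries) the componentwise
    posterior median is used as the plug-in point instead.
    """
    draws = np.atleast_2d(np.asarray(draws, dtype=float))
    if draws.shape[0] < 100:
        raise ValueError(f"need >= 100 posterior draws for DIC, got {draws.shape[0]}")
    dev = -2.0 * models.loglik(s, model_tag, draws)
    d_bar = float(dev.mean())
    theta_hat = draws.mean(axis=0)
    if not models.in_space(model_tag, theta_hat):
        logger.info("%s: posterior mean outside the space; using median for DIC plug-in", s.snp_id)
        theta_hat = np.median(draws, axis=0)
    if not models.in_space(model_tag, theta_hat):
        # fall back to the draw with the lowest deviance
        theta_hat = draws[int(np.argmin(dev))]
    d_hat = float(-2.0 * models.loglik(s, model_tag, theta_hat[None, :])[0])
    return 2.0 * d_bar - d_hat


@dataclass
class PatternCall:
    """Winning-model pattern label for one SNP."""

    label: str  # overall | stallion | mare | additive | heterosis | additive+heterosis | genotypic
    family: str  # allelic | genotypic
    model_tag: str
    magnitude: float
    tie: bool
    dic_gap: float  # winner-to-runner-up DIC gap

    @property
    def display(self) -> str:
        return f"{self.label} (tie-default)" if self.tie else self.label


def select_pattern(
    allelic: InferenceResult,
    parent_specific: InferenceResult,
    genotypic: InferenceResult,
    dic_margin: float = 3.0,
) -> PatternCall:
    """Classify the inheritance pattern by DIC model comparison.

    The model with the lowest DIC wins if it beats the runner-up by more than
    ``dic_margin`` units; otherwise the simplest model within the margin is
    taken and the call flagged as a tie. Within the allelic family the
    stallion/mare/overall sub-label follows which parent-specific parameter's
    95% interval excludes zero; a genotypic winner is labelled additive and/or
    heterosis the same way (heterosis = the dominance interval excludes zero).
    """
    results = {r.model_tag: r for r in (allelic, parent_specific, genotypic)}
    dics = {tag: results[tag].dic for tag in _SIMPLICITY}
    ordered = sorted(dics, key=dics.get)
    best, runner = ordered[0], ordered[1]
    gap = dics[runner] - dics[best]
    tie = gap <= dic_margin
    if tie:
        within = [t for t in _SIMPLICITY if dics[t] - dics[ordered[0]] <= dic_margin]
        winner_tag = within[0]
    else:
        winner_tag = best
    win = results[winner_tag]
    if winner_tag == "allelic_overall":
        label, family = "overall", "allelic"
        magnitude = abs(float(win.posterior["alpha"]["mean"]))
    elif winner_tag == "allelic_parent_specific":
        family = "allelic"
        s_excl = win.posterior.ci_excludes_zero("alpha_s")
        d_excl = win.posterior.ci_excludes_zero("alpha_d")
        if s_excl and not d_excl:
            label = "stallion"
            magnitude = abs(float(win.posterior["alpha_s"]["mean"]))
        elif d_excl and not s_excl:
            label = "mare"
            magnitude = abs(float(win.posterior["alpha_d"]["mean"]))
        else:
            label = "overall"
            magnitude = abs(float(allelic.posterior["alpha"]["mean"]))
    else:
        family = "genotypic"
        a_excl = win.posterior.ci_excludes_zero("alpha_g")
        d_excl = win.posterior.ci_excludes_zero("delta_g")
        mag_a = abs(float(win.posterior["alpha_g"]["mean"]))
        mag_d = abs(float(win.posterior["delta_g"]["mean"]))
        if a_excl and d_excl:
            label, magnitude = "additive+heterosis", max(mag_a, mag_d)
        elif d_excl:
            label, magnitude = "heterosis", mag_d
        elif a_excl:
            label, magnitude = "additive", mag_a
        else:
            label, magnitude = "genotypic", max(mag_a, mag_d)
    return PatternCall(
        label=label,
        family=family,
        model_tag=winner_tag,
        magnitude=magnitude,
        tie=tie,
        dic_gap=gap,
    )


def fit_model(
    s: TransmissionSummary,
    model_tag: str,
    cfg: McmcConfig | None = None,
    grid_size: int = 201,
) -> InferenceResult:
    """MCMC posterior + Bayes factor + DIC for one model."""
    cfg = cfg or McmcConfig()
    post = run_mcmc(s, model_tag, cfg, keep_draws=True)
    bf = bayes_factor(s, model_tag, grid_size=grid_size)
    dic = compute_dic(s, post.draws, model_tag)
    return InferenceResult(model_tag=model_tag, posterior=post, log10_bf=bf, dic=dic)
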