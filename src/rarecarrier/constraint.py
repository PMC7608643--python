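"""Gene-constraint selection metrics: o/e ratios with exact Poisson CIs,
signed depletion Z-scores, and pLI via a three-class Poisson mixture fit by
expectation-maximization.

The mixture follows the ExAC/gnomAD constraint framework: a gene's observed
loss-of-function (LOF) count is modelled as Poisson with rate
``factor_k * expected`` under three selection classes — null (no constraint,
factor 1.0), recessive-like depletion (factor 0.463), and haploinsufficient
(factor 0.089).  pLI is the posterior probability of the haploinsufficient
class; pLI >= 0.9 labels a gene LOF-intolerant and pLI <= 0.1 LOF-tolerant.

The depletion Z-score is ``(expected - observed) / sqrt(expected)``:
positive for depletion (fewer variants than expected, suggesting negative
selection), negative for excess.  Published per-gene Z values are often
additionally divided by empirically fitted per-class constants; the divisor
is exposed in the API (default 1, i.e. the raw Z).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import gamma, poisson

MUTATION_CLASSES = ("syn", "mis", "lof")

# Per-class Poisson rate depletion factors (null, recessive, haploinsufficient)
DEFAULT_FACTORS = (1.0, 0.463, 0.089)

# Significance thresholds for constraint labels: |Z| > 3.71 (synonymous) and
# |Z| > 3.09 (missense) mark significant deviation; CI upper bound < 0.35
# marks strong intolerance.
Z_THRESHOLD_SYN = 3.71
Z_THRESHOLD_MIS = 3.09
OE_STRONG_INTOLERANCE = 0.35
PLI_TOLERANT = 0.1
PLI_INTOLERANT = 0.9


@dataclass(frozen=True)
class GeneCounts:
    gene: str
    obs_syn: int
    exp_syn: float
    obs_mis: int
    exp_mis: float
    obs_lof: int
    exp_lof: float

    def __post_init__(self) -> None:
        for cls in MUTATION_CLASSES:
            obs = getattr(self, f"obs_{cls}")
            exp = getattr(self, f"exp_{cls}")
            if obs < 0:
                raise ValueError(f"{self.gene}: obs_{cls} < 0")
            if exp <= 0:
                raise ValueError(f"{self.gene}: exp_{cls} <= 0")

    def obs(self, cls: str) -> int:
        return getattr(self, f"obs_{cls}")

    def exp(self, cls: str) -> float:
        return getattr(self, f"exp_{cls}")


def read_gene_counts(path: str | Path) -> list[GeneCounts]:
    df = pd.read_csv(path, sep="\t")
    return [
        GeneCounts(
            gene=str(r["gene"]),
            obs_syn=int(r["obs_syn"]),
            exp_syn=float(r["exp_syn"]),
            obs_mis=int(r["obs_mis"]),
            exp_mis=float(r["exp_mis"]),
            obs_lof=int(r["obs_lof"]),
            exp_lof=float(r["exp_lof"]),
        )
        for r in df.to_dict("records")
    ]


def oe_ratio(obs: int, exp: float, level: float = 0.90) -> tuple[float, tuple[float, float]]:
    """Observed/expected ratio with an exact Poisson-rate confidence interval.

    The CI is the gamma-quantile (exact) interval on the Poisson mean of the
    observed count, divided by the expectation: lower bound
    ``Gamma(obs).ppf(alpha/2)`` (0 when obs = 0) and upper bound
    ``Gamma(obs + 1).ppf(1 - alpha/2)``.
    """
    if exp <= 0:
        raise ValueError("expected count must be positive")
    alpha = 1.0 - level
    lo = 0.0 if obs == 0 else float(gamma.ppf(alpha / 2, obs)) / exp
    hi = float(gamma.ppf(1 - alpha / 2, obs + 1)) / exp
    return obs / exp, (lo, hi)


def z_score(obs: int, exp: float, divisor: float = 1.0) -> float:
    """Signed depletion Z: (exp - obs)/sqrt(exp), optionally rescaled.

    Positive = depletion (obs below expectation), negative = excess.
    """
    if exp <= 0:
        raise ValueError("expected count must be positive")
    if divisor <= 0:
        raise ValueError("divisor must be positive")
    return (exp - obs) / np.sqrt(exp) / divisor


@dataclass(frozen=True)
class EMConfig:
    factors: tuple[float, float, float] = DEFAULT_FACTORS
    priors: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    estimate_priors: bool = True
    tol: float = 1e-8
    max_iter: int = 1000
    seed: int | None = None  # for optional prior jitter
    jitter: float = 0.0

    def __post_init__(self) -> None:
        f = self.factors
        if not (f[0] > f[1] > f[2] > 0):
            raise ValueError("depletion factors must be strictly decreasing")
        if abs(sum(self.priors) - 1.0) > 1e-9:
            raise ValueError("priors must sum to 1")


@dataclass(frozen=True)
class EMResult:
    posteriors: pd.DataFrame  # index gene; columns pNull, pRec, pLI
    priors: tuple[float, float, float]
    loglik_trace: tuple[float, ...]
    converged: bool
    n_iter: int


def pli_em(genes: list[GeneCounts], config: EMConfig | None = None) -> EMResult:
    """Fit the three-class Poisson mixture to per-gene LOF counts.

    E-step: posterior responsibilities of (null, recessive,
    haploinsufficient) per gene under Poisson(obs; factor_k * exp).
    M-step: mixture weights = mean responsibilities.  Likelihoods are kept in
    log space with log-sum-exp; the log-likelihood is non-decreasing every
    iteration.  With ``estimate_priors=False`` the posteriors are a single
    Bayes update under the fixed priors.
    """
    config = config or EMConfig()
    if not genes:
        raise ValueError("at least one gene required")
    obs = np.array([g.obs_lof for g in genes], dtype=float)
    exp = np.array([g.exp_lof for g in genes], dtype=float)
    factors = np.asarray(config.factors)
    # loglik[g, k] = log Poisson(obs_g ; factor_k * exp_g)
    loglik = poisson.logpmf(obs[:, None], factors[None, :] * exp[:, None])

    priors = np.asarray(config.priors, dtype=float)
    if config.jitter > 0:
        rng = np.random.default_rng(config.seed)
        priors = priors + rng.uniform(0, config.jitter, size=3)
        priors = priors / priors.sum()

    def e_step(pi):
        logpost = np.log(pi)[None, :] + loglik
        norm = logsumexp(logpost, axis=1, keepdims=True)
        return np.exp(logpost - norm), float(norm.sum())

    if not config.estimate_priors:
        resp, ll = e_step(priors)
        trace = (ll,)
        converged = True
        n_iter = 0
    else:
        trace_list = []
        resp, ll = e_step(priors)
        trace_list.append(ll)
        converged = False
        n_iter = 0
        for n_iter in range(1, config.max_iter + 1):
            priors = resp.mean(axis=0)
            resp, ll_new = e_step(priors)
            trace_list.append(ll_new)
            if ll_new - ll < config.tol * max(1.0, abs(ll)):
                converged = True
                ll = ll_new
                break
            ll = ll_new
        trace = tuple(trace_list)

    posteriors = pd.DataFrame(
        resp,
        index=[g.gene for g in genes],
        columns=["pNull", "pRec", "pLI"],
    )
    posteriors.index.name = "gene"
    return EMResult(
        posteriors=posteriors,
        priors=tuple(float(p) for p in priors),
        loglik_trace=trace,
        converged=converged,
        n_iter=n_iter,
    )


@dataclass(frozen=True)
class ConstraintResult:
    gene: str
    oe: dict[str, float]
    oe_ci90: dict[str, tuple[float, float]]
    z: dict[str, float]
    z_divisor: dict[str, float]
    pNull: float
    pRec: float
    pLI: float
    labels: tuple[str, ...]


def constraint_labels(
    pli: float,
    z_syn: float,
    z_mis: float,
    oe_ci90_lof_high: float,
) -> tuple[str, ...]:
    """Threshold labels: LOF tolerance from pLI, synonymous/missense
    significance from |Z| (sign gives direction), strong intolerance from
    the LOF o/e CI upper bound."""
    labels = []
    if pli <= PLI_TOLERANT:
        labels.append("lof_tolerant")
    if pli >= PLI_INTOLERANT:
        labels.append("lof_intolerant")
    if abs(z_syn) > Z_THRESHOLD_SYN:
        labels.append(
            "syn_depleted" if z_syn > 0 else "syn_elevated"
        )
    if abs(z_mis) > Z_THRESHOLD_MIS:
        labels.append(
            "mis_depleted" if z_mis > 0 else "mis_elevated"
        )
    if oe_ci90_lof_high < OE_STRONG_INTOLERANCE:
        labels.append("strong_lof_intolerance")
    return tuple(labels)


def gene_constraint(
    counts: GeneCounts,
    config: EMConfig | None = None,
    z_divisors: dict[str, float] | None = None,
    cohort: list[GeneCounts] | None = None,
) -> ConstraintResult:
    """Full constraint result for one gene.

    With a single gene the mixture priors cannot be estimated, so the pLI
    posteriors come from a fixed-prior Bayes update (uniform by default);
    passing ``cohort`` fits the mixture across genes and reads this gene's
    posterior from the joint fit.
    """
    config = config or EMConfig()
    z_divisors = z_divisors or {}
    oe: dict[str, float] = {}
    ci: dict[str, tuple[float, float]] = {}
    z: dict[str, float] = {}
    for cls in MUTATION_CLASSES:
        o, c = oe_ratio(counts.obs(cls), counts.exp(cls))
        oe[cls] = o
        ci[cls] = c
        z[cls] = z_score(
            counts.obs(cls), counts.exp(cls), z_divisors.get(cls, 1.0)
        )
    if cohort is not None:
        em = pli_em(cohort, config)
        post = em.posteriors.loc[counts.gene]
    else:
        single = EMConfig(
            factors=config.factors,
            priors=config.priors,
            estimate_priors=False,
            tol=config.tol,
            max_iter=config.max_iter,
        )
        em = pli_em([counts], single)
        post = em.posteriors.iloc[0]
    labels = constraint_labels(
        pli=float(post["pLI"]),
        z_syn=z["syn"],
        z_mis=z["mis"],
        oe_ci90_lof_high=ci["lof"][1],
    )
    return ConstraintResult(
        gene=counts.gene,
        oe=oe,
        oe_ci90=ci,
        z=z,
        z_divisor={cls: z_divisors.get(cls, 1.0) for cls in MUTATION_CLASSES},
        pNull=float(post["pNull"]),
        pRec=float(post["pRec"]),
        pLI=float(post["pLI"]),
        labels=labels,
    )
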