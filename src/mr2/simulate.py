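"""Synthetic two-sample GWAS generator for multi-response MR.

Generates individual-level data under a structural model in which n
independent biallelic variants instrument p correlated exposures, an
unmeasured confounder U affects both exposures and outcomes, an unmeasured
pleiotropic pathway A (a descendant of the instruments) affects all
outcomes, and the q outcome error vectors may themselves be correlated:

    Y_k = X theta_k + A theta_a + U theta_yu + eps_k,   k = 1..q.

Summary statistics are then extracted exactly as a GWAS consortium would
produce them: per-variant univariable OLS regressions, with the exposure
associations estimated on one half of the cohort and the outcome
associations on the other half (two-sample design), with configurable
overlap between the per-outcome samples.

Five named scenarios cover the canonical stress tests: a global null,
confounding only, a shared undirected pleiotropic pathway, a shared
directed (level-increasing) pathway, and directly correlated outcome
errors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .data import SummaryData

logger = logging.getLogger(__name__)

SCENARIOS = ("I_null", "II_confounding", "III_undirected_pleiotropy",
             "IV_directed_pleiotropy", "V_dependence")

#: scenario -> (theta_a if unset, r_y if unset)
_SCENARIO_OPEN = {
    "I_null": (0.0, 0.6),
    "II_confounding": (0.0, 0.0),
    "III_undirected_pleiotropy": (1.0, 0.0),
    "IV_directed_pleiotropy": (1.0, 0.0),
    "V_dependence": (0.0, 0.6),
}


class ConfigError(ValueError):
    """The scenario configuration is internally inconsistent or infeasible."""


@dataclass
class ScenarioConfig:
    """All knobs of the generating model.

    The defaults reproduce the reference simulation design: n=100 IVs,
    p=15 exposures, q=5 outcomes, N=100,000 individuals split half/half
    between the exposure and outcome GWAS, 30% of exposure-outcome pairs
    carrying a direct causal effect, exposure correlation r_x=0.6 and
    confounder effects theta_xu=2, theta_yu=1.  ``theta_a`` and ``r_y``
    default per scenario (see ``_SCENARIO_OPEN``); pass explicit values to
    override.

    Conventions for quantities the reference design leaves open:

    * ``h_gx`` — heritability of each exposure through the n instruments
      (default 0.125, i.e. per-variant F-statistic ~ 60 at N/2=50,000).
    * ``h_ga`` — heritability of the pleiotropic pathway through the same
      instruments (default 0.005: the pathway is polygenic and only weakly
      tagged by the selected IVs, but its genetic component is what keeps
      residual correlation alive under zero sample overlap).
    * ``effect_range`` — nonzero direct effects are Uniform(0.1, 0.3),
      positive by default; ``signed_effects=True`` randomizes signs.
    * ``h_x`` — Var(X theta_k) / (Var(X theta_k) + delta_k^2): fraction of
      outcome variance explained by the exposures relative to exposure
      signal plus idiosyncratic noise (pathway and confounder variance sit
      on top of this budget).
    """

    scenario: str = "II_confounding"
    n_variants: int = 100
    n_exposures: int = 15
    n_outcomes: int = 5
    n_individuals: int = 100_000
    sparsity: float = 0.30
    r_x: float = 0.6
    r_y: float | None = None
    theta_xu: float = 2.0
    theta_yu: float = 1.0
    theta_a: float | None = None
    mu_a: float = 0.0
    sigma2_a: float = 1.0
    h_x: float = 0.10
    overlap: float = 1.0
    effect_range: tuple = (0.1, 0.3)
    signed_effects: bool = False
    h_gx: float = 0.125
    h_ga: float = 0.005
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ConfigError(f"unknown scenario {self.scenario!r}; "
                              f"choose from {SCENARIOS}")
        theta_a_default, r_y_default = _SCENARIO_OPEN[self.scenario]
        if self.theta_a is None:
            self.theta_a = theta_a_default
        if self.r_y is None:
            self.r_y = r_y_default
        if self.scenario == "I_null":
            # the null removes the confounder entirely
            self.theta_xu = 0.0
            self.theta_yu = 0.0
        if not 0.0 <= self.sparsity <= 1.0:
            raise ConfigError("sparsity must be in [0, 1]")
        if not (abs(self.r_x) < 1 and abs(self.r_y) < 1):
            raise ConfigError("|r_x| and |r_y| must be < 1")
        if self.n_outcomes > 1 and self.r_y <= -1.0 / (self.n_outcomes - 1):
            raise ConfigError(
                f"equicorrelation r_y={self.r_y} is not positive definite "
                f"for q={self.n_outcomes}")
        if not 0.0 <= self.overlap <= 1.0:
            raise ConfigError("overlap must be in [0, 1]")
        if self.n_individuals % 2:
            raise ConfigError("n_individuals must be even (two-sample split)")
        if self.r_x < 0:
            raise ConfigError("r_x must be non-negative in this generator")
        if self.r_x + self.h_gx > 1.0:
            raise ConfigError(
                f"r_x + h_gx = {self.r_x + self.h_gx:.3f} > 1: the shared "
                "non-genetic factor and the genetic component would exceed "
                "the unit variance budget")
        if not 0 < self.h_x < 1:
            raise ConfigError("h_x must be in (0, 1)")
        lo, hi = self.effect_range
        if not (0 <= lo <= hi):
            raise ConfigError("effect_range must satisfy 0 <= lo <= hi")

    @property
    def is_null(self) -> bool:
        return self.scenario == "I_null"

    @property
    def directed_pathway(self) -> bool:
        return self.scenario == "IV_directed_pleiotropy"

    def with_(self, **kw) -> "ScenarioConfig":
        """Copy with fields replaced (scenario resolution re-runs)."""
        base = {k: getattr(self, k) for k in self.__dataclass_fields__}
        base.update(kw)
        return ScenarioConfig(**base)


@dataclass
class TruthRecord:
    """Ground truth for evaluating selection and estimation."""

    true_theta: np.ndarray    # (q, p)
    true_gamma: np.ndarray    # (q, p) bool
    scenario: str

    def to_dict(self) -> dict:
        return {"scenario": self.scenario,
                "true_theta": self.true_theta.tolist(),
                "true_gamma": self.true_gamma.astype(int).tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "TruthRecord":
        return cls(np.asarray(d["true_theta"], dtype=float),
                   np.asarray(d["true_gamma"], dtype=bool),
                   d["scenario"])


@dataclass
class IndividualData:
    """One realization of the individual-level generating model."""

    genotypes: np.ndarray     # (N, n) dosages in {0,1,2}
    exposures: np.ndarray     # (N, p)
    pathway: np.ndarray       # (N,)
    confounder: np.ndarray    # (N,)
    outcomes: np.ndarray      # (N, q)
    true_theta: np.ndarray    # (q, p)
    true_gamma: np.ndarray    # (q, p) bool
    delta2: np.ndarray        # (q,) outcome error variances
    allele_freqs: np.ndarray  # (n,)
    config: ScenarioConfig = field(repr=False, default=None)

    @property
    def truth(self) -> TruthRecord:
        return TruthRecord(self.true_theta, self.true_gamma,
                           self.config.scenario if self.config else "unknown")


def _draw_effects(cfg: ScenarioConfig, rng) -> np.ndarray:
    p, q = cfg.n_exposures, cfg.n_outcomes
    theta = np.zeros((q, p))
    if cfg.is_null or cfg.sparsity == 0:
        return theta
    m = int(round(cfg.sparsity * p * q))
    pos = rng.choice(p * q, size=m, replace=False)
    lo, hi = cfg.effect_range
    mag = rng.uniform(lo, hi, size=m)
    if cfg.signed_effects:
        mag *= rng.choice([-1.0, 1.0], size=m)
    theta.flat[pos] = mag
    return theta


def simulate_individual(config: ScenarioConfig) -> IndividualData:
    """Draw one individual-level dataset under the configured scenario.

    Exposures are built as X_j = sqrt(r_x) S + sqrt(1-r_x) F_j where the
    shared factor S and the idiosyncratic factors F_j are independent
    unit-variance traits, each with heritability ``h_gx`` through the
    instruments.  This makes both the phenotypic and the genetic pairwise
    exposure correlation equal to r_x.  The confounder U loads on the
    non-genetic part of S in proportion to theta_xu, so it confounds every
    exposure, and enters each outcome directly with coefficient theta_yu.

    The pleiotropic pathway A has a small genetic component (``h_ga``) plus
    noise; in the directed scenario it is passed through absolute value so
    that A_l > 0 for every individual, while the undirected scenario keeps
    it symmetric about zero.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    N, n, p, q = cfg.n_individuals, cfg.n_variants, cfg.n_exposures, cfg.n_outcomes

    freqs = rng.uniform(0.05, 0.5, size=n)
    G = rng.binomial(2, freqs, size=(N, n)).astype(np.float64)
    var_g = 2.0 * freqs * (1.0 - freqs)

    # variant effect scale so that Var(G w) = h for each trait
    def genetic_component(h):
        w = rng.normal(0.0, np.sqrt(h / (n * var_g)))
        return G @ w

    U = rng.normal(size=N)
    # shared factor S: heritable + non-genetic part carrying the confounder
    s_gen = genetic_component(cfg.h_gx)
    s_scale = math.sqrt(cfg.theta_xu ** 2 + 1.0)
    s_ng = (cfg.theta_xu * U + rng.normal(size=N)) / s_scale
    S = s_gen + math.sqrt(1.0 - cfg.h_gx) * s_ng

    F = np.empty((N, p))
    for j in range(p):
        F[:, j] = genetic_component(cfg.h_gx) \
            + math.sqrt(1.0 - cfg.h_gx) * rng.normal(size=N)
    X = math.sqrt(cfg.r_x) * S[:, None] + math.sqrt(1.0 - cfg.r_x) * F

    # pleiotropic pathway: weakly tagged by the IVs, noise on top
    a_gen = genetic_component(cfg.h_ga * cfg.sigma2_a)
    A = cfg.mu_a + a_gen \
        + math.sqrt((1.0 - cfg.h_ga) * cfg.sigma2_a) * rng.normal(size=N)
    if cfg.directed_pathway:
        A = np.abs(A)

    theta = _draw_effects(cfg, rng)
    gamma = theta != 0.0

    # residual scale: exposures explain h_x of (signal + idiosyncratic noise)
    cov_x = (1.0 - cfg.r_x) * np.eye(p) + cfg.r_x * np.ones((p, p))
    var_sig = np.einsum("kp,pj,kj->k", theta, cov_x, theta)
    delta2 = np.where(var_sig > 0, var_sig * (1.0 - cfg.h_x) / cfg.h_x, 1.0)

    delta = np.sqrt(delta2)
    Z = rng.normal(size=(N, q))
    if cfg.r_y != 0.0:
        corr = (1.0 - cfg.r_y) * np.eye(q) + cfg.r_y * np.ones((q, q))
        L = np.linalg.cholesky(corr)
        eps = (Z @ L.T) * delta
    else:
        eps = Z * delta

    Y = X @ theta.T + np.outer(A, np.full(q, cfg.theta_a)) \
        + np.outer(U, np.full(q, cfg.theta_yu)) + eps

    return IndividualData(G, X, A, U, Y, theta, gamma, delta2, freqs, cfg)


def _per_variant_ols(G, T):
    """Univariable OLS of each column of T on each column of G.

    Returns (beta, se) of shape (n_variants, n_traits); the textbook
    per-variant GWAS regression with an intercept.
    """
    M = G.shape[0]
    Gc = G - G.mean(axis=0)
    Tc = T - T.mean(axis=0)
    ssg = np.einsum("ij,ij->j", Gc, Gc)
    beta = (Gc.T @ Tc) / ssg[:, None]
    sst = np.einsum("ij,ij->j", Tc, Tc)
    rss = np.maximum(sst[None, :] - beta ** 2 * ssg[:, None], 0.0)
    se = np.sqrt(rss / (M - 2) / ssg[:, None])
    return beta, se


def extract_summary(ind: IndividualData, config: ScenarioConfig | None = None
                    ) -> SummaryData:
    """Two-sample summary-statistic extraction.

    The first N/2 individuals provide the exposure GWAS, the second N/2 the
    outcome GWAS.  ``config.overlap`` controls how much the per-outcome
    samples share: at 1.0 all q outcomes are measured on the same
    individuals, at 0.0 each outcome uses a disjoint subsample of size
    N/(2q), and intermediate values interpolate (each outcome sample has a
    common block of fraction ``overlap`` plus its own disjoint block).
    """
    cfg = config or ind.config
    G, X, Y = ind.genotypes, ind.exposures, ind.outcomes
    N, n = G.shape
    q = Y.shape[1]
    N2 = N // 2
    if N < 2 * n:
        raise ConfigError(f"need at least 2 individuals per variant in each "
                          f"sample; N={N}, n={n}")

    bx, sx = _per_variant_ols(G[:N2], X[:N2])

    ov = cfg.overlap
    if ov == 1.0:
        by, sy = _per_variant_ols(G[N2:], Y[N2:])
    else:
        nk = int(N2 / (ov + q * (1.0 - ov)))
        shared = int(round(ov * nk))
        chunk = nk - shared
        if nk < n + 2:
            raise ConfigError(
                f"overlap={ov} leaves only {nk} individuals per outcome "
                f"sample, fewer than n_variants+2={n + 2}")
        by = np.empty((n, q))
        sy = np.empty((n, q))
        for k in range(q):
            lo = N2 + shared + k * chunk
            idx = np.r_[N2:N2 + shared, lo:lo + chunk]
            b, s = _per_variant_ols(G[idx], Y[idx, k:k + 1])
            by[:, k], sy[:, k] = b[:, 0], s[:, 0]

    return SummaryData(
        variant_ids=[f"rs{i + 1}" for i in range(n)],
        exposure_names=[f"X{j + 1}" for j in range(X.shape[1])],
        outcome_names=[f"Y{k + 1}" for k in range(q)],
        beta_x=bx, se_x=sx, beta_y=by, se_y=sy)


def simulate_summary(config: ScenarioConfig):
    """Convenience: individual-level draw + two-sample extraction.

    Returns ``(SummaryData, TruthRecord)``.
    """
    ind = simulate_individual(config)
    return extract_summary(ind, config), ind.truth


def theoretical_residual_correlation(theta_a, sigma2_a, delta2_k, delta2_k2,
                                     sigma_kk2) -> float:
    """Closed-form residual correlation between two outcomes.

    The correlation between the residuals of the summary-level
    multi-response model induced by a shared pleiotropic pathway with
    effect theta_a and variance sigma2_a, on top of a direct covariance
    sigma_kk2 between the individual-level outcome errors (variances
    delta2_k, delta2_k2):

        rho = (theta_a^2 sigma2_a + sigma_kk')
              / sqrt(theta_a^2 sigma2_a + delta_k^2)
              / sqrt(theta_a^2 sigma2_a + delta_k'^2)

    It is zero only when both the shared pathway and the error covariance
    vanish, is always positive under shared pleiotropy regardless of the
    sign of theta_a, and increases monotonically with |theta_a| when
    sigma_kk2 = 0.
    """
    if delta2_k <= 0 or delta2_k2 <= 0 or sigma2_a < 0:
        raise ValueError("variances must be positive")
    shared = theta_a ** 2 * sigma2_a
    rho = (shared + sigma_kk2) \
        / math.sqrt((shared + delta2_k) * (shared + delta2_k2))
    if not -1.0 <= rho <= 1.0:
        raise ValueError(
            f"inconsistent covariance: implied correlation {rho:.4f} is "
            "outside [-1, 1]; check sigma_kk2 against the error variances")
    return rho


def residual_correlation_arguments(config: ScenarioConfig) -> dict:
    """Map the generator to the argument slots of the closed-form correlation.

    At the summary level every *shared* stochastic component of the outcome
    GWAS contributes to the residual covariance between two outcomes: the
    genetic part of the pathway (shared through the variant effects
    themselves, hence independent of sample overlap), and — in proportion
    to the sample overlap — the non-genetic part of the pathway, the
    confounder, the non-genetic parts of the exposures carried into the
    outcomes by their causal effects, and any direct error correlation r_y.
    The per-variant OLS noise of the *exposure* GWAS is likewise shared
    across outcomes because a single exposure dataset serves all of them.

    This function accumulates those pieces in closed form (using
    expectations over the random effect draw) and returns a dict with keys
    ``theta_a, sigma2_a, delta2, sigma_kk2`` suitable for
    :func:`theoretical_residual_correlation`.  All variances are in units
    of the per-variant OLS scale v_i^2.
    """
    cfg = config
    p, q, n = cfg.n_exposures, cfg.n_outcomes, cfg.n_variants
    N2 = cfg.n_individuals // 2
    ov = cfg.overlap
    nk = N2 if ov == 1.0 else int(N2 / (ov + q * (1.0 - ov)))

    lo, hi = cfg.effect_range
    e_th = 0.0 if cfg.signed_effects else (lo + hi) / 2.0
    e_th2 = (lo * lo + lo * hi + hi * hi) / 3.0
    s = 0.0 if cfg.is_null else cfg.sparsity
    sum_th = p * s * e_th                      # E sum_j theta_kj

    # E[theta_k' C theta_k'' ] under the non-genetic exposure covariance
    diag_ng = 1.0 - cfg.h_gx
    off_ng = cfg.r_x * (1.0 - cfg.h_gx)
    qf_same = diag_ng * p * s * e_th2 + off_ng * p * (p - 1) * (s * e_th) ** 2
    qf_diff = diag_ng * p * (s * e_th) ** 2 \
        + off_ng * p * (p - 1) * (s * e_th) ** 2

    # confounder loading on each exposure's non-genetic part
    b = math.sqrt(cfg.r_x * (1.0 - cfg.h_gx)) * cfg.theta_xu \
        / math.sqrt(cfg.theta_xu ** 2 + 1.0)

    # idiosyncratic outcome noise from the h_x budget
    var_sig = p * s * e_th2 + cfg.r_x * p * (p - 1) * (s * e_th) ** 2
    delta2 = var_sig * (1.0 - cfg.h_x) / cfg.h_x if var_sig > 0 else 1.0

    ta2 = cfg.theta_a ** 2
    sigma2_a_eff = cfg.h_ga * cfg.sigma2_a * nk / n \
        + ov * (1.0 - cfg.h_ga) * cfg.sigma2_a

    cross_u = 2.0 * cfg.theta_yu * b * sum_th
    sigma_kk2 = (1.0 + ov) * qf_diff \
        + ov * (cfg.theta_yu ** 2 + cross_u + cfg.r_y * delta2)
    delta2_eff = 2.0 * qf_same + cfg.theta_yu ** 2 + cross_u + delta2

    return {"theta_a": cfg.theta_a if ta2 > 0 else 0.0,
            "sigma2_a": sigma2_a_eff, "delta2": delta2_eff,
            "sigma_kk2": sigma_kk2}


def expected_residual_correlation(config: ScenarioConfig) -> float:
    """Closed-form prediction of the generator's residual correlation."""
    a = residual_correlation_arguments(config)
    return theoretical_residual_correlation(
        a["theta_a"], a["sigma2_a"], a["delta2"], a["delta2"], a["sigma_kk2"])


def empirical_outcome_correlation(summary: SummaryData) -> np.ndarray:
    """Raw pairwise correlation between the outcome summary statistics.

    This mixes exposure-driven correlation with residual correlation and
    therefore upper-bounds what remains after conditioning on the exposures
    whenever the direct effects are predominantly concordant.
    """
    by = summary.beta_y
    if by.shape[0] < 3:
        raise ValueError("need at least 3 variants to estimate a correlation")
    sd = by.std(axis=0)
    if np.any(sd == 0):
        k = int(np.argmax(sd == 0))
        raise ValueError(f"outcome column {k} is constant; "
                         "correlation undefined")
    C = np.corrcoef(by, rowvar=False)
    C = (C + C.T) / 2.0
    np.fill_diagonal(C, 1.0)
    return C
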