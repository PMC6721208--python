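"""The rule-set probability model.

A rule is a conjunction of detectors; a rule set feeds the truth values of
its rules into a Bayesian logistic regression:

    y_i ~ Bernoulli(p_i),  p_i = logistic(psi_i),
    psi = beta0 + A(R, x) beta (+ covariates),
    beta0, beta_k ~ Normal(0, sigma_b^2),
    R ~ pi(R).

The prior over rule sets pi(R) is a mixture placing probability Theta_empty
on the empty set, with non-empty sets built by drawing a size K (truncated
negative binomial), per-rule lengths (truncated geometric), and detectors
from an assignment distribution factorized over window duration and taxon.

Normalization conventions: a rule is a *set* of distinct detectors obtained
by conditioning i.i.d. assignment draws on distinctness (normalizer: the
elementary symmetric polynomial e_L of the detector probabilities); a rule
set is the *multiset* of K i.i.d. rule draws (multinomial permutation
coefficient).  With these conventions the prior sums to exactly 1 over the
enumerable state space, and ``sample_prior`` and ``log_prior_ruleset`` are
mutually consistent.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from .pool import AVERAGE, DetectorPool, window_average, window_slope

__all__ = [
    "Rule",
    "RuleSet",
    "PriorConfig",
    "DetectorPrior",
    "detector_satisfied",
    "truth_matrix",
    "linear_predictor",
    "log_likelihood",
    "log_prior_ruleset",
    "sample_prior",
]

Rule = tuple  # sorted tuple of detector indices into the pool


@dataclass
class RuleSet:
    """A list of rules; each rule is a sorted tuple of detector indices.

    Rule order is meaningful only for pairing with regression weights; the
    prior and all summaries treat the rule list as a multiset.
    """

    rules: list = field(default_factory=list)

    def __post_init__(self):
        self.rules = [tuple(sorted(r)) for r in self.rules]
        for r in self.rules:
            if len(r) == 0:
                raise ValueError("rules must be non-empty")
            if len(set(r)) != len(r):
                raise ValueError(f"duplicate detectors within rule {r}")

    @property
    def K(self):
        return len(self.rules)

    @property
    def n_detectors(self):
        return sum(len(r) for r in self.rules)

    @property
    def is_empty(self):
        return not self.rules

    def canonical(self) -> tuple:
        return tuple(sorted(self.rules))

    def __eq__(self, other):
        return isinstance(other, RuleSet) and self.canonical() == other.canonical()

    def __hash__(self):
        return hash(self.canonical())


@dataclass
class PriorConfig:
    """Hyperparameters of the rule-set prior and regression prior.

    ``theta_empty``: prior probability of the empty rule set.
    ``nb_r, nb_p``: negative binomial (r, p) for the number of rules K,
    truncated to [1, k_max]; the defaults (r=1, p=1/3) give a mean non-empty
    size of about 1.5.
    ``geom_q``: success probability of the truncated geometric rule-length
    prior on [1, l_max] (default mean about 1.5).
    ``sigma_b``: prior s.d. of the regression weights (log odds-ratios); the
    default is calibrated on no-signal synthetic cohorts so that the Bayes
    factor favors the empty rule set when the labels carry no information
    (a wider weight prior strengthens the Occam penalty per added rule).
    ``alpha_dur, alpha_tax``: Dirichlet hyperprior concentrations for the
    window-duration and taxon weight vectors of the detector assignment;
    moderately stiff defaults limit rich-get-richer feedback on spurious
    detectors while still letting repeatedly used clades gain weight.
    """

    theta_empty: float = 0.5
    nb_r: float = 1.0
    nb_p: float = 1.0 / 3.0
    k_max: int = 10
    geom_q: float = 2.0 / 3.0
    l_max: int = 5
    sigma_b: float = 5.0
    alpha_dur: float = 10.0
    alpha_tax: float = 10.0

    def __post_init__(self):
        if not 0 < self.theta_empty < 1:
            raise ValueError("theta_empty must be in (0, 1)")
        if not 0 < self.nb_p < 1 or not 0 < self.geom_q < 1:
            raise ValueError("nb_p and geom_q must be in (0, 1)")
        if self.sigma_b <= 0:
            raise ValueError("sigma_b must be positive")
        if self.k_max < 1 or self.l_max < 1:
            raise ValueError("k_max and l_max must be >= 1")

    def ruleset_size_logpmf(self) -> np.ndarray:
        """log pmf of K over 1..k_max (truncated negative binomial)."""
        cached = self.__dict__.get("_size_logpmf")
        if cached is not None:
            return cached
        k = np.arange(1, self.k_max + 1)
        logw = (
            gammaln(k + self.nb_r)
            - gammaln(self.nb_r)
            - gammaln(k + 1)
            + k * math.log(self.nb_p)
            + self.nb_r * math.log1p(-self.nb_p)
        )
        out = logw - logsumexp(logw)
        self.__dict__["_size_logpmf"] = out
        return out

    def rule_length_logpmf(self, l_max_eff=None) -> np.ndarray:
        """log pmf of L over 1..l_max (truncated geometric)."""
        lmax = self.l_max if l_max_eff is None else min(self.l_max, l_max_eff)
        cache = self.__dict__.setdefault("_len_logpmf", {})
        if lmax in cache:
            return cache[lmax]
        l = np.arange(1, lmax + 1)
        logw = (l - 1) * math.log1p(-self.geom_q) + math.log(self.geom_q)
        out = logw - logsumexp(logw)
        cache[lmax] = out
        return out


class DetectorPrior:
    """Detector-assignment distribution over a pool, given weight vectors.

    A detector is drawn by sampling a window-duration category from
    ``w_dur``, then a taxon from ``w_tax`` renormalized over the taxa having
    detectors at that duration, then uniformly among matching detectors.
    All computations are per-category, so evaluation is O(#categories).
    """

    def __init__(self, pool: DetectorPool, w_dur=None, w_tax=None):
        self.pool = pool
        n_dur = len(pool.durations)
        n_tax = len(pool.taxa)
        self.w_dur = (
            np.full(n_dur, 1.0 / n_dur) if w_dur is None else np.asarray(w_dur, float)
        )
        self.w_tax = (
            np.full(n_tax, 1.0 / n_tax) if w_tax is None else np.asarray(w_tax, float)
        )
        if len(self.w_dur) != n_dur or len(self.w_tax) != n_tax:
            raise ValueError("weight vector lengths do not match the pool")
        self._refresh()

    def _refresh(self):
        pool = self.pool
        # availability: taxa having >= 1 detector at each duration
        avail = np.zeros((len(pool.durations), len(pool.taxa)), dtype=bool)
        avail[pool.cat_dur_idx, pool.cat_taxon] = True
        self.S_dur = avail @ self.w_tax  # renormalizer per duration category
        self.cat_logp = (
            np.log(self.w_dur[pool.cat_dur_idx])
            + np.log(self.w_tax[pool.cat_taxon])
            - np.log(self.S_dur[pool.cat_dur_idx])
            - np.log(pool.cat_count)
        )
        # elementary symmetric polynomials e_1..e_Lmax of detector probabilities
        # via Newton's identities on per-category power sums
        p_cat = np.exp(self.cat_logp)
        max_l = 12  # covers any practical l_max
        power_sums = np.array([
            (pool.cat_count * p_cat**k).sum() for k in range(1, max_l + 1)
        ])
        e = np.zeros(max_l + 1)
        e[0] = 1.0
        for k in range(1, max_l + 1):
            acc = 0.0
            for i in range(1, k + 1):
                acc += (-1) ** (i - 1) * e[k - i] * power_sums[i - 1]
            e[k] = acc / k
        self.log_esp = np.full(max_l + 1, -np.inf)
        pos = e > 0
        self.log_esp[pos] = np.log(e[pos])

    def with_weights(self, w_dur, w_tax) -> "DetectorPrior":
        return DetectorPrior(self.pool, w_dur, w_tax)

    def detector_logp(self, det_idx) -> np.ndarray:
        return self.cat_logp[self.pool.cat_of_det[np.asarray(det_idx)]]

    def rule_logp(self, rule: Rule) -> float:
        """log prior probability of a rule as a set of distinct detectors."""
        L = len(rule)
        if not np.isfinite(self.log_esp[L]):
            return -np.inf
        return float(self.detector_logp(list(rule)).sum() - self.log_esp[L])

    def sample_detector(self, rng) -> int:
        probs = np.exp(self.cat_logp) * self.pool.cat_count
        cat = rng.choice(len(probs), p=probs / probs.sum())
        members = self.pool.cat_members[cat]
        return int(members[rng.integers(len(members))])

    def sample_rule(self, length, rng) -> Rule:
        """Rejection-sample ``length`` distinct detectors (i.i.d. conditioned
        on distinctness, matching ``rule_logp``)."""
        if length > self.pool.n_detectors:
            raise ValueError("rule length exceeds pool size")
        while True:
            draws = [self.sample_detector(rng) for _ in range(length)]
            if len(set(draws)) == length:
                return tuple(sorted(draws))


def detector_satisfied(cohort, subject, pool: DetectorPool, det_idx: int) -> bool:
    """Evaluate one detector directly from the cohort data (strict
    comparisons: a statistic exactly at the threshold satisfies neither
    direction)."""
    taxon_idx, window, kind = pool.combos[pool.det_combo[det_idx]]
    times, values = cohort.series(subject, cohort.taxa[taxon_idx])
    stat = (
        window_average(times, values, window)
        if kind == AVERAGE
        else window_slope(times, values, window)
    )
    theta = pool.det_threshold[det_idx]
    return bool(stat > theta) if pool.det_above[det_idx] else bool(stat < theta)


def rule_truth(pool: DetectorPool, rule: Rule) -> np.ndarray:
    """Truth vector of a rule (conjunction) over the pool's subjects."""
    return pool.truth[list(rule)].all(axis=0)


def truth_matrix(pool: DetectorPool, ruleset: RuleSet) -> np.ndarray:
    """N_subjects x K binary matrix; empty rule sets give zero columns."""
    if ruleset.is_empty:
        return np.zeros((pool.n_subjects, 0), dtype=np.int8)
    cols = [rule_truth(pool, r) for r in ruleset.rules]
    return np.column_stack(cols).astype(np.int8)


def linear_predictor(A, beta0, beta, covariates=None, beta_cov=None) -> np.ndarray:
    """psi_i = beta0 + sum_k A_ik beta_k (+ covariate terms)."""
    A = np.asarray(A, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if A.shape[1] != beta.shape[0]:
        raise ValueError(f"A has {A.shape[1]} columns but beta has {beta.shape[0]}")
    psi = beta0 + A @ beta
    if covariates is not None:
        psi = psi + np.asarray(covariates, float) @ np.asarray(beta_cov, float)
    return psi


def log_likelihood(y, psi) -> float:
    """Bernoulli-logistic log likelihood, overflow-safe."""
    y = np.asarray(y, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if y.shape != psi.shape:
        raise ValueError("y and psi must have equal length")
    return float((y * psi - np.logaddexp(0.0, psi)).sum())


def log_prior_ruleset(
    ruleset: RuleSet, pool: DetectorPool, config: PriorConfig,
    detector_prior: DetectorPrior | None = None,
) -> float:
    """Log prior probability of a rule set (see module docstring for the
    normalization conventions)."""
    if ruleset.is_empty:
        return math.log(config.theta_empty)
    dp = detector_prior or DetectorPrior(pool)
    K = ruleset.K
    if K > config.k_max:
        return -np.inf
    size_logpmf = config.ruleset_size_logpmf()
    l_max_eff = min(config.l_max, pool.n_detectors)
    len_logpmf = config.rule_length_logpmf(l_max_eff)
    out = math.log1p(-config.theta_empty) + size_logpmf[K - 1]
    # multiset permutation coefficient K! / prod(multiplicities!)
    out += gammaln(K + 1)
    for mult in Counter(ruleset.rules).values():
        out -= gammaln(mult + 1)
    for rule in ruleset.rules:
        L = len(rule)
        if L > l_max_eff:
            return -np.inf
        out += len_logpmf[L - 1] + dp.rule_logp(rule)
    return float(out)


def sample_prior(
    pool: DetectorPool, config: PriorConfig, rng,
    detector_prior: DetectorPrior | None = None,
    n_covariates: int = 0,
):
    """Draw (RuleSet, beta0, beta, beta_cov) from the prior."""
    dp = detector_prior or DetectorPrior(pool)
    beta0 = rng.normal(0.0, config.sigma_b)
    beta_cov = rng.normal(0.0, config.sigma_b, size=n_covariates)
    if rng.random() < config.theta_empty:
        return RuleSet([]), float(beta0), np.empty(0), beta_cov
    size_pmf = np.exp(config.ruleset_size_logpmf())
    K = 1 + rng.choice(config.k_max, p=size_pmf)
    l_max_eff = min(config.l_max, pool.n_detectors)
    len_pmf = np.exp(config.rule_length_logpmf(l_max_eff))
    rules = []
    for _ in range(K):
        L = 1 + rng.choice(l_max_eff, p=len_pmf)
        rules.append(dp.sample_rule(L, rng))
    beta = rng.normal(0.0, config.sigma_b, size=K)
    return RuleSet(rules), float(beta0), beta, beta_cov
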