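"""Posterior sampling over (rule set, regression coefficients, hyperparameters).

The sampler alternates three blocks per iteration:

1. a Polya-Gamma augmented Gibbs draw of the regression coefficients, which
   is exact because the augmented conditional is Gaussian;
2. a fixed number of Metropolis-Hastings proposals on the rule set, drawn
   from four move types (replace / remove / add / move a detector), with the
   proposal ratio computed exactly from the forward and reverse selection
   probabilities; rule births draw their weight from the prior, so the
   weight-prior terms cancel from the acceptance ratio (a reversible-jump
   move with identity mapping);
3. a Metropolised-Gibbs update of the detector-assignment weight vectors
   using their conjugate Dirichlet form as the proposal (exact, and reduces
   to pure Gibbs when every taxon has detectors at every window duration).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .model import (
    DetectorPrior,
    PriorConfig,
    RuleSet,
    log_likelihood,
    log_prior_ruleset,
)
from .pg import pg_vector
from .pool import DetectorPool

__all__ = [
    "gibbs_update_coefficients",
    "propose_ruleset_move",
    "mh_accept",
    "update_hyperparameters",
    "run_mcmc",
    "diagnostics",
    "Trace",
    "TraceSample",
]


# --- coefficient block ------------------------------------------------------


def gibbs_update_coefficients(A, y, omega, sigma_b, rng, covariates=None):
    """Exact conditional Gaussian draw of (beta0, beta[, beta_cov]).

    With X = [1 | A | covariates], kappa = y - 1/2 and Omega = diag(omega),
    the conditional is Normal(m, V) with V = (X' Omega X + I/sigma_b^2)^-1
    and m = V X' kappa.
    """
    A = np.asarray(A, dtype=float)
    y = np.asarray(y, dtype=float)
    omega = np.asarray(omega, dtype=float)
    parts = [np.ones((A.shape[0], 1)), A]
    if covariates is not None:
        parts.append(np.asarray(covariates, dtype=float))
    X = np.hstack(parts)
    d = X.shape[1]
    prec = X.T @ (omega[:, None] * X) + np.eye(d) / sigma_b**2
    kappa = y - 0.5
    chol = np.linalg.cholesky(prec)
    m = np.linalg.solve(prec, X.T @ kappa)
    z = rng.standard_normal(d)
    draw = m + np.linalg.solve(chol.T, z)
    n_rules = A.shape[1]
    beta0 = float(draw[0])
    beta = draw[1 : 1 + n_rules]
    beta_cov = draw[1 + n_rules :]
    return beta0, beta, beta_cov


# --- rule-set moves ---------------------------------------------------------

MOVE_TYPES = ("replace", "remove", "add", "move")


def _move_counts(rules, P, l_max, k_max):
    """Per-type counts of legal proposals from a state."""
    D = sum(len(r) for r in rules)
    repl_positions = [
        (k, j) for k, r in enumerate(rules) if P - len(r) >= 1 for j in range(len(r))
    ]
    add_targets = [
        k for k, r in enumerate(rules) if len(r) < l_max and P - len(r) >= 1
    ]
    if len(rules) < k_max and P >= 1:
        add_targets.append(-1)  # -1 = create a new rule of length 1
    move_pairs = []
    for k, r in enumerate(rules):
        if len(r) < 2:
            continue
        for j, d in enumerate(r):
            for b, rb in enumerate(rules):
                if b != k and len(rb) < l_max and d not in rb:
                    move_pairs.append((k, j, b))
    legal = []
    if repl_positions:
        legal.append("replace")
    if D >= 1:
        legal.append("remove")
    if add_targets:
        legal.append("add")
    if move_pairs:
        legal.append("move")
    return {
        "D": D,
        "replace": repl_positions,
        "add": add_targets,
        "move": move_pairs,
        "legal": legal,
    }


def _sample_candidate(rng, P, exclude):
    # uniform over pool \ exclude, by rejection
    while True:
        d = int(rng.integers(P))
        if d not in exclude:
            return d


def propose_ruleset_move(ruleset: RuleSet, pool: DetectorPool, rng,
                         l_max: int, k_max: int):
    """Propose a single-detector change to the rule set.

    Returns ``(new_rules, tag, beta_op, log_q_ratio)`` where ``beta_op`` is
    None, ("delete", k) or ("append",) describing the weight bookkeeping, and
    ``log_q_ratio`` = log q(R'->R) - log q(R->R') accounts exactly for the
    forward and reverse selection probabilities.  When a rule set contains
    identical rules, several selections map to the same resulting multiset;
    both directions are therefore weighted by the multiplicity of the rule
    type acted upon, so the ratio is the exact total transition probability
    ratio.
    """
    from collections import Counter

    rules = list(ruleset.rules)
    P = pool.n_detectors
    info = _move_counts(rules, P, l_max, k_max)
    legal = info["legal"]
    if not legal:
        raise ValueError("no legal rule-set move (empty rule set and pool)")
    move = legal[int(rng.integers(len(legal)))]
    log_T = math.log(len(legal))
    beta_op = None
    mult = Counter(rules)

    if move == "replace":
        positions = info["replace"]
        k, j = positions[int(rng.integers(len(positions)))]
        rule = rules[k]
        d_new = _sample_candidate(rng, P, set(rule))
        new_rule = tuple(sorted(set(rule) - {rule[j]} | {d_new}))
        new_rules = rules[:k] + [new_rule] + rules[k + 1 :]
        log_q_fwd = (
            math.log(mult[rule]) - log_T
            - math.log(len(positions)) - math.log(P - len(rule))
        )
        info_r = _move_counts(new_rules, P, l_max, k_max)
        log_q_rev = (
            math.log(Counter(new_rules)[new_rule])
            - math.log(len(info_r["legal"]))
            - math.log(len(info_r["replace"]))
            - math.log(P - len(new_rule))
        )

    elif move == "remove":
        D = info["D"]
        flat = [(k, j) for k, r in enumerate(rules) for j in range(len(r))]
        k, j = flat[int(rng.integers(D))]
        rule = rules[k]
        if len(rule) > 1:
            new_rule = tuple(v for i, v in enumerate(rule) if i != j)
            new_rules = rules[:k] + [new_rule] + rules[k + 1 :]
            rev_cand = P - len(new_rule)
            m_rev = Counter(new_rules)[new_rule]
        else:
            new_rules = rules[:k] + rules[k + 1 :]
            beta_op = ("delete", k)
            rev_cand = P
            m_rev = 1  # reverse creates a new rule: a single selection
        log_q_fwd = math.log(mult[rule]) - log_T - math.log(D)
        info_r = _move_counts(new_rules, P, l_max, k_max)
        log_q_rev = (
            math.log(m_rev)
            - math.log(len(info_r["legal"]))
            - math.log(len(info_r["add"]))
            - math.log(rev_cand)
        )

    elif move == "add":
        targets = info["add"]
        tgt = targets[int(rng.integers(len(targets)))]
        if tgt == -1:
            d_new = _sample_candidate(rng, P, set())
            new_rules = rules + [(d_new,)]
            beta_op = ("append",)
            cand = P
            m_fwd = 1
            m_rev = Counter(new_rules)[(d_new,)]
        else:
            rule = rules[tgt]
            d_new = _sample_candidate(rng, P, set(rule))
            new_rule = tuple(sorted(rule + (d_new,)))
            new_rules = rules[:tgt] + [new_rule] + rules[tgt + 1 :]
            cand = P - len(rule)
            m_fwd = mult[rule]
            m_rev = Counter(new_rules)[new_rule]
        log_q_fwd = (
            math.log(m_fwd) - log_T - math.log(len(targets)) - math.log(cand)
        )
        info_r = _move_counts(new_rules, P, l_max, k_max)
        log_q_rev = (
            math.log(m_rev)
            - math.log(len(info_r["legal"])) - math.log(info_r["D"])
        )

    else:  # move a detector between rules
        pairs = info["move"]
        k, j, b = pairs[int(rng.integers(len(pairs)))]
        d = rules[k][j]
        src, tgt_rule = rules[k], rules[b]
        new_src = tuple(v for i, v in enumerate(src) if i != j)
        new_tgt = tuple(sorted(tgt_rule + (d,)))
        new_rules = list(rules)
        new_rules[k] = new_src
        new_rules[b] = new_tgt
        log_q_fwd = (
            math.log(mult[src] * mult[tgt_rule]) - log_T - math.log(len(pairs))
        )
        info_r = _move_counts(new_rules, P, l_max, k_max)
        mult_r = Counter(new_rules)
        log_q_rev = (
            math.log(mult_r[new_tgt] * mult_r[new_src])
            - math.log(len(info_r["legal"])) - math.log(len(info_r["move"]))
        )

    return new_rules, move, beta_op, log_q_rev - log_q_fwd


def mh_accept(log_post_new, log_post_old, log_proposal_ratio, rng) -> bool:
    """Metropolis-Hastings acceptance decision."""
    if not np.isfinite(log_post_old):
        raise ValueError("current log posterior must be finite")
    if log_post_new == -np.inf:
        return False
    log_alpha = log_post_new - log_post_old + log_proposal_ratio
    return log_alpha >= 0 or rng.random() < math.exp(log_alpha)


# --- hyperparameter block ---------------------------------------------------


def _log_dirichlet(w, alpha):
    alpha = np.asarray(alpha, dtype=float)
    w = np.clip(np.asarray(w, dtype=float), 1e-300, None)
    return float(
        gammaln(alpha.sum()) - gammaln(alpha).sum() + ((alpha - 1) * np.log(w)).sum()
    )


def _weights_loglik(ruleset, dp: DetectorPrior):
    """Terms of the rule-set prior that depend on the weight vectors."""
    out = 0.0
    for rule in ruleset.rules:
        out += dp.rule_logp(rule)
    return out


def update_hyperparameters(
    ruleset: RuleSet, pool: DetectorPool, config: PriorConfig,
    dp: DetectorPrior, rng,
):
    """Metropolised-Gibbs update of (w_dur, w_tax) with a conjugate
    Dirichlet(prior + counts) proposal; exact for the renormalized two-stage
    assignment distribution.  With an empty rule set this draws from the
    hyperprior."""
    n_dur = len(pool.durations)
    n_tax = len(pool.taxa)
    cnt_dur = np.zeros(n_dur)
    cnt_tax = np.zeros(n_tax)
    for rule in ruleset.rules:
        for d in rule:
            cnt_dur[pool.det_dur_idx[d]] += 1
            cnt_tax[pool.det_taxon[d]] += 1
    a_dur = np.full(n_dur, config.alpha_dur) + cnt_dur
    a_tax = np.full(n_tax, config.alpha_tax) + cnt_tax
    w_dur_new = rng.dirichlet(a_dur)
    w_tax_new = rng.dirichlet(a_tax)
    dp_new = dp.with_weights(w_dur_new, w_tax_new)
    prior_dur = np.full(n_dur, config.alpha_dur)
    prior_tax = np.full(n_tax, config.alpha_tax)

    def log_target(d):
        return (
            _log_dirichlet(d.w_dur, prior_dur)
            + _log_dirichlet(d.w_tax, prior_tax)
            + _weights_loglik(ruleset, d)
        )

    def log_proposal(d):
        return _log_dirichlet(d.w_dur, a_dur) + _log_dirichlet(d.w_tax, a_tax)

    log_alpha = (log_target(dp_new) - log_proposal(dp_new)) - (
        log_target(dp) - log_proposal(dp)
    )
    if log_alpha >= 0 or rng.random() < math.exp(log_alpha):
        return dp_new, True
    return dp, False


# --- trace ------------------------------------------------------------------


@dataclass
class TraceSample:
    rules: tuple  # tuple of rules (each a tuple of detector indices)
    beta0: float
    beta: np.ndarray
    beta_cov: np.ndarray
    w_dur: np.ndarray
    w_tax: np.ndarray
    log_posterior: float
    iteration: int

    @property
    def K(self):
        return len(self.rules)

    @property
    def n_detectors(self):
        return sum(len(r) for r in self.rules)

    @property
    def is_empty(self):
        return not self.rules

    def canonical(self):
        return tuple(sorted(self.rules))


@dataclass
class Trace:
    samples: list
    burn_in: int
    seed: int
    acceptance: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def post_burn_in(self):
        return self.samples[self.burn_in :]

    def save(self, path):
        with open(path, "w", encoding="utf-8") as fh:
            header = {
                "burn_in": self.burn_in, "seed": self.seed,
                "acceptance": {
                    k: list(v) for k, v in sorted(self.acceptance.items())
                },
                "meta": self.meta,
            }
            fh.write(json.dumps(header, sort_keys=True) + "\n")
            for s in self.samples:
                fh.write(json.dumps({
                    "rules": [list(r) for r in s.rules],
                    "beta0": s.beta0,
                    "beta": list(s.beta),
                    "beta_cov": list(s.beta_cov),
                    "w_dur": list(s.w_dur),
                    "w_tax": list(s.w_tax),
                    "log_posterior": s.log_posterior,
                    "iteration": s.iteration,
                }) + "\n")

    @classmethod
    def load(cls, path):
        with open(path, encoding="utf-8") as fh:
            header = json.loads(fh.readline())
            samples = []
            for line in fh:
                d = json.loads(line)
                samples.append(TraceSample(
                    rules=tuple(tuple(r) for r in d["rules"]),
                    beta0=d["beta0"],
                    beta=np.array(d["beta"]),
                    beta_cov=np.array(d["beta_cov"]),
                    w_dur=np.array(d["w_dur"]),
                    w_tax=np.array(d["w_tax"]),
                    log_posterior=d["log_posterior"],
                    iteration=d["iteration"],
                ))
        return cls(
            samples, header["burn_in"], header["seed"],
            {k: tuple(v) for k, v in header["acceptance"].items()},
            header.get("meta", {}),
        )


# --- main loop --------------------------------------------------------------


def run_mcmc(
    cohort,
    pool: DetectorPool,
    prior: PriorConfig | None = None,
    n_samples: int = 50_000,
    seed: int = 0,
    thin: int = 1,
    burn_in: int | None = None,
    n_mh: int = 10,
    likelihood_on: bool = True,
    update_hypers: bool = True,
    fixed_weights=None,
    progress: bool = False,
) -> Trace:
    """Sample the posterior over (R, beta, hyperparameters).

    Each iteration runs one coefficient block update, ``n_mh`` rule-set
    proposals and one hyperparameter sweep; ``burn_in`` defaults to half the
    retained samples.  With ``likelihood_on=False`` the chain targets the
    prior (used by the prior-recovery diagnostic).  ``fixed_weights`` (a
    (w_dur, w_tax) pair) pins the detector-assignment weights, which also
    disables their updates.
    """
    prior = prior or PriorConfig()
    rng = np.random.default_rng(seed)
    y = cohort.y.astype(float)
    N = len(y)
    covariates = (
        cohort.covariates.to_numpy(dtype=float)
        if getattr(cohort, "covariates", None) is not None
        else None
    )
    n_cov = 0 if covariates is None else covariates.shape[1]

    if fixed_weights is not None:
        dp = DetectorPrior(pool, *fixed_weights)
        update_hypers = False
    else:
        dp = DetectorPrior(
            pool,
            rng.dirichlet(np.full(len(pool.durations), prior.alpha_dur)),
            rng.dirichlet(np.full(len(pool.taxa), prior.alpha_tax)),
        )

    ruleset = RuleSet([])
    beta0 = rng.normal(0.0, prior.sigma_b)
    beta = np.empty(0)
    beta_cov = rng.normal(0.0, prior.sigma_b, size=n_cov)
    truth_cols = []  # per-rule boolean truth vectors, aligned with rules

    def psi_of(cols, b0, b, b_cov):
        psi = np.full(N, b0)
        for col, bk in zip(cols, b):
            psi = psi + bk * col
        if covariates is not None:
            psi = psi + covariates @ b_cov
        return psi

    def loglik(cols, b0, b, b_cov):
        if not likelihood_on:
            return 0.0
        return log_likelihood(y, psi_of(cols, b0, b, b_cov))

    log_prior_R = log_prior_ruleset(ruleset, pool, prior, dp)
    cur_ll = loglik(truth_cols, beta0, beta, beta_cov)

    acceptance = {t: [0, 0] for t in MOVE_TYPES}
    acceptance["hyper"] = [0, 0]
    samples = []
    total_iters = n_samples * thin
    for it in range(total_iters):
        # 1. coefficients
        if likelihood_on:
            psi = psi_of(truth_cols, beta0, beta, beta_cov)
            omega = pg_vector(psi, rng)
            A = (
                np.column_stack(truth_cols).astype(float)
                if truth_cols else np.zeros((N, 0))
            )
            beta0, beta, beta_cov = gibbs_update_coefficients(
                A, y, omega, prior.sigma_b, rng, covariates
            )
        else:
            beta0 = rng.normal(0.0, prior.sigma_b)
            beta = rng.normal(0.0, prior.sigma_b, size=len(truth_cols))
            beta_cov = rng.normal(0.0, prior.sigma_b, size=n_cov)
        cur_ll = loglik(truth_cols, beta0, beta, beta_cov)

        # 2. rule-set moves
        for _ in range(n_mh):
            new_rules, tag, beta_op, log_q_ratio = propose_ruleset_move(
                ruleset, pool, rng, prior.l_max, prior.k_max
            )
            acceptance[tag][1] += 1
            new_ruleset = RuleSet(new_rules)
            new_beta = beta
            if beta_op is None:
                pass
            elif beta_op[0] == "delete":
                k = beta_op[1]
                new_beta = np.delete(beta, k)
            else:  # append: weight for the newborn rule, drawn from its prior
                new_beta = np.append(beta, rng.normal(0.0, prior.sigma_b))
            new_cols = [
                pool.truth[list(r)].all(axis=0) for r in new_rules
            ]
            new_ll = loglik(new_cols, beta0, new_beta, beta_cov)
            new_lp = log_prior_ruleset(new_ruleset, pool, prior, dp)
            if mh_accept(new_ll + new_lp, cur_ll + log_prior_R, log_q_ratio, rng):
                acceptance[tag][0] += 1
                ruleset, beta, truth_cols = new_ruleset, new_beta, new_cols
                cur_ll, log_prior_R = new_ll, new_lp

        # 3. hyperparameters
        if update_hypers:
            acceptance["hyper"][1] += 1
            dp, accepted = update_hyperparameters(ruleset, pool, prior, dp, rng)
            if accepted:
                acceptance["hyper"][0] += 1
            log_prior_R = log_prior_ruleset(ruleset, pool, prior, dp)

        if (it + 1) % thin == 0:
            log_beta_prior = (
                -0.5 * (beta0**2 + (beta**2).sum() + (beta_cov**2).sum())
                / prior.sigma_b**2
                - 0.5 * (1 + len(beta) + n_cov) * math.log(2 * math.pi * prior.sigma_b**2)
            )
            samples.append(TraceSample(
                rules=tuple(ruleset.rules),
                beta0=float(beta0),
                beta=beta.copy(),
                beta_cov=beta_cov.copy(),
                w_dur=dp.w_dur.copy(),
                w_tax=dp.w_tax.copy(),
                log_posterior=float(cur_ll + log_prior_R + log_beta_prior),
                iteration=it,
            ))
    bi = n_samples // 2 if burn_in is None else burn_in
    return Trace(
        samples, bi, seed,
        {k: tuple(v) for k, v in acceptance.items()},
        {
            "n_samples": n_samples, "thin": thin, "n_mh": n_mh,
            "likelihood_on": likelihood_on,
        },
    )


# --- diagnostics ------------------------------------------------------------


def _autocorr_time(x, max_lag=None):
    """Integrated autocorrelation time (initial positive sequence estimator)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4 or np.var(x) == 0:
        return np.nan
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1 :] / (np.arange(n, 0, -1) * np.var(x))
    tau = 1.0
    for lag in range(1, max_lag or n // 4):
        if acf[lag] <= 0:
            break
        tau += 2.0 * acf[lag]
    return tau


def _geweke_z(x, first=0.1, last=0.5):
    x = np.asarray(x, dtype=float)
    n = len(x)
    a = x[: max(1, int(first * n))]
    b = x[-max(1, int(last * n)) :]

    def spectral_var(v):
        # batch-means estimate of the long-run variance
        nb = max(1, int(math.sqrt(len(v))))
        bs = len(v) // nb
        if bs < 1:
            return np.var(v)
        means = [v[i * bs : (i + 1) * bs].mean() for i in range(nb)]
        return bs * np.var(means)

    denom = math.sqrt(spectral_var(a) / len(a) + spectral_var(b) / len(b))
    if denom == 0:
        return np.nan
    return (a.mean() - b.mean()) / denom


def diagnostics(trace: Trace, burn_in: int | None = None) -> dict:
    """Mixing diagnostics over the post-burn-in trace."""
    bi = trace.burn_in if burn_in is None else burn_in
    if bi >= len(trace.samples):
        raise ValueError(
            f"burn-in {bi} >= trace length {len(trace.samples)}"
        )
    post = trace.samples[bi:]
    series = {
        "log_posterior": np.array([s.log_posterior for s in post]),
        "K": np.array([s.K for s in post], dtype=float),
        "n_detectors": np.array([s.n_detectors for s in post], dtype=float),
    }
    report = {"acceptance_rates": {}, "series": {}}
    for tag, (acc, tot) in trace.acceptance.items():
        report["acceptance_rates"][tag] = acc / tot if tot else np.nan
    for name, x in series.items():
        degenerate = bool(np.var(x) == 0)
        half = len(x) // 2
        report["series"][name] = {
            "mean": float(x.mean()),
            "autocorr_time": float(_autocorr_time(x)),
            "geweke_z": float(_geweke_z(x)) if not degenerate else np.nan,
            "split_half_mean_diff": float(x[:half].mean() - x[half:].mean())
            if half else np.nan,
            "degenerate": degenerate,
        }
    return report
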