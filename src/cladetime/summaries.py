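"""Distilling an MCMC trace into reportable results.

Provides the point-estimate rule set, clusters of alternative rule sets,
Bayes factors (empty rule set, per-taxon, and per taxon x basic-window
heatmap), per-subject predictions (point or posterior-ensemble mode), and
stratified cross-validated F1 at the 0.5 probability threshold.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold

from .mcmc import Trace, run_mcmc
from .model import DetectorPrior, PriorConfig, sample_prior
from .pool import AVERAGE, DetectorPool, PoolParams, build_pool, window_average, window_slope

__all__ = [
    "point_estimate",
    "cluster_rule_sets",
    "bayes_factor_empty",
    "bayes_factor_feature",
    "predict",
    "cross_validate",
    "heatmap_export",
    "SummaryReport",
    "summarize",
    "Prediction",
    "CrossValidationResult",
]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


# --- point estimate ---------------------------------------------------------


def point_estimate(trace: Trace):
    """(rules, beta0, beta, beta_cov) summarizing the posterior mode.

    Empty if the posterior probability of the empty rule set exceeds 0.5;
    otherwise the most frequent sampled rule set among those whose total
    detector count equals the posterior mode of that count, with the highest
    log-posterior coefficients sampled alongside it.  Ties are broken toward
    fewer detectors / lexicographically smaller rule sets.
    """
    post = trace.post_burn_in()
    if not post:
        raise ValueError("empty trace (all samples within burn-in)")
    empties = [s for s in post if s.is_empty]
    if len(empties) / len(post) > 0.5:
        best = max(empties, key=lambda s: s.log_posterior)
        return (), best.beta0, np.empty(0), best.beta_cov
    non_empty = [s for s in post if not s.is_empty]
    counts = Counter(s.n_detectors for s in non_empty)
    top = max(counts.values())
    d_star = min(d for d, c in counts.items() if c == top)
    candidates = [s for s in non_empty if s.n_detectors == d_star]
    freq = Counter(s.canonical() for s in candidates)
    top = max(freq.values())
    r_star = min(r for r, c in freq.items() if c == top)
    matching = [s for s in candidates if s.canonical() == r_star]
    best = max(matching, key=lambda s: s.log_posterior)
    return best.rules, best.beta0, best.beta.copy(), best.beta_cov.copy()


# --- clustering -------------------------------------------------------------


def _interval_jaccard(w1, w2) -> float:
    inter = min(w1.t1, w2.t1) - max(w1.t0, w2.t0)
    if inter <= 0:
        return 0.0
    union = max(w1.t1, w2.t1) - min(w1.t0, w2.t0)
    return inter / union


class _UnionFind:
    def __init__(self, items):
        self.parent = {i: i for i in items}

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i, j):
        self.parent[self.find(i)] = self.find(j)


def cluster_rule_sets(trace: Trace, pool: DetectorPool, overlap_frac: float = 0.5):
    """Three-level agglomeration of the sampled rule sets.

    Detectors cluster when they share taxon and kind and their windows have
    interval-Jaccard overlap >= ``overlap_frac`` (thresholds ignored,
    transitively closed); rules cluster when their detectors' clusters form
    the same multiset; rule sets likewise over rule clusters.  Each cluster
    reports its most frequent member rule set and its posterior mass.
    """
    post = trace.post_burn_in()
    if not post:
        raise ValueError("empty trace")
    dets = sorted({d for s in post for r in s.rules for d in r})
    uf = _UnionFind(dets)
    by_group = {}
    for d in dets:
        taxon_idx, window, kind = pool.combos[pool.det_combo[d]]
        by_group.setdefault((taxon_idx, kind), []).append((d, window))
    for members in by_group.values():
        for i, (d1, w1) in enumerate(members):
            for d2, w2 in members[i + 1 :]:
                if _interval_jaccard(w1, w2) >= overlap_frac:
                    uf.union(d1, d2)
    det_cluster = {d: uf.find(d) for d in dets}

    def ruleset_key(sample):
        return tuple(sorted(
            tuple(sorted(det_cluster[d] for d in r)) for r in sample.rules
        ))

    keys = [ruleset_key(s) for s in post]
    freq = Counter(keys)
    clusters = []
    for key, count in freq.most_common():
        members = [s for s, k in zip(post, keys) if k == key]
        rep = Counter(s.canonical() for s in members).most_common(1)[0][0]
        clusters.append({
            "key": key,
            "probability": count / len(post),
            "representative": rep,
            "is_empty": key == (),
        })
    return clusters, det_cluster


# --- Bayes factors ----------------------------------------------------------


def _smoothed_odds(n_yes, n_no):
    if n_yes == 0 or n_no == 0:
        n_yes, n_no = n_yes + 0.5, n_no + 0.5
    return n_yes / n_no, n_yes, n_no


def bayes_factor_empty(trace: Trace, prior: PriorConfig):
    """Bayes factor of the empty rule set versus any non-empty rule set,
    estimated as posterior odds over prior odds, with additive smoothing
    when a category has no samples.  Returns (BF, naive MC standard error).
    """
    post = trace.post_burn_in()
    n_e = sum(1 for s in post if s.is_empty)
    n_n = len(post) - n_e
    odds, a, b = _smoothed_odds(n_e, n_n)
    prior_odds = prior.theta_empty / (1.0 - prior.theta_empty)
    bf = odds / prior_odds
    se = bf * math.sqrt(1.0 / a + 1.0 / b)
    return bf, se


def simulate_prior_rulesets(pool: DetectorPool, prior: PriorConfig,
                            n_sims: int = 100_000, seed: int = 20_177):
    """Rule sets drawn from the prior (hyperparameters marginalized by
    drawing the assignment weights from their hyperprior per draw); cached on
    the pool object."""
    key = (
        n_sims, seed, prior.theta_empty, prior.nb_r, prior.nb_p, prior.k_max,
        prior.geom_q, prior.l_max, prior.alpha_dur, prior.alpha_tax,
    )
    cache = getattr(pool, "_prior_sim_cache", None)
    if cache is not None and cache[0] == key:
        return cache[1]
    rng = np.random.default_rng(seed)
    draws = []
    for _ in range(n_sims):
        dp = DetectorPrior(
            pool,
            rng.dirichlet(np.full(len(pool.durations), prior.alpha_dur)),
            rng.dirichlet(np.full(len(pool.taxa), prior.alpha_tax)),
        )
        rs, _, _, _ = sample_prior(pool, prior, rng, detector_prior=dp)
        draws.append(tuple(rs.rules))
    pool._prior_sim_cache = (key, draws)
    return draws


def _clade_cover(cohort):
    """taxon -> set of retained taxa in its clade (itself and descendants);
    a detector on taxon u "applies to" feature taxon t iff t is in u's clade,
    i.e. u is t or one of t's ancestors."""
    children = {}
    for t, p in cohort.parent.items():
        children.setdefault(p, []).append(t)
    cover = {}

    def descend(t):
        if t in cover:
            return cover[t]
        out = {t}
        for c in children.get(t, []):
            out = out | descend(c)
        cover[t] = out
        return out

    for t in cohort.taxa:
        descend(t)
    return cover


def _detector_applies(pool, cohort, cover, det, leaf=None, basic_idx=None):
    taxon = cohort.taxa[pool.det_taxon[det]]
    if leaf is not None and leaf not in cover[taxon]:
        return False
    if basic_idx is not None:
        w = pool.window_of(det)
        if not (w.i0 <= basic_idx <= w.i0 + w.n_basic - 1):
            return False
    return True


def _inclusion_fraction(rulesets, pool, cohort, cover, leaf, basic_idx):
    hits = 0
    for rules in rulesets:
        for r in rules:
            if any(
                _detector_applies(pool, cohort, cover, d, leaf, basic_idx)
                for d in r
            ):
                hits += 1
                break
    return hits, len(rulesets)


def bayes_factor_feature(
    trace: Trace, prior: PriorConfig, pool: DetectorPool, cohort,
    taxon=None, basic_idx=None, n_prior_sims: int = 100_000, prior_seed: int = 20_177,
):
    """Bayes factor for ">= 1 detector in R applies to the feature" (a taxon
    and/or one basic window; a detector applies to a taxon when its own taxon
    is that taxon or an ancestor of it) versus "none", as posterior odds over
    prior odds estimated by prior simulation."""
    cover = _clade_cover(cohort)
    leaf = taxon
    post_rules = [s.rules for s in trace.post_burn_in()]
    prior_rules = simulate_prior_rulesets(pool, prior, n_prior_sims, prior_seed)
    h_post, n_post = _inclusion_fraction(post_rules, pool, cohort, cover, leaf, basic_idx)
    h_prior, n_prior = _inclusion_fraction(prior_rules, pool, cohort, cover, leaf, basic_idx)
    if h_prior == 0:
        if h_post == 0:
            raise ValueError(
                "feature never included a priori or a posteriori; "
                "Bayes factor undefined"
            )
        raise ValueError("zero prior inclusion probability; Bayes factor undefined")
    post_odds, _, _ = _smoothed_odds(h_post, n_post - h_post)
    prior_odds, _, _ = _smoothed_odds(h_prior, n_prior - h_prior)
    return post_odds / prior_odds


def heatmap_export(
    trace: Trace, pool: DetectorPool, cohort, prior: PriorConfig,
    path=None, n_prior_sims: int = 100_000, prior_seed: int = 20_177,
) -> pd.DataFrame:
    """Bayes factors for every (retained leaf taxon) x (basic window) cell.

    Rows follow the tree traversal order of the retained leaves, columns the
    basic windows in time order.  If ``path`` is given, writes CSV and JSON.
    """
    cover = _clade_cover(cohort)
    leaves = cohort.leaves  # already in tree-traversal order of cohort.taxa
    n_w = pool.params.n_w
    post_rules = [s.rules for s in trace.post_burn_in()]
    prior_rules = simulate_prior_rulesets(pool, prior, n_prior_sims, prior_seed)

    def hit_matrix(rulesets):
        hits = np.zeros((len(leaves), n_w))
        leaf_idx = {l: i for i, l in enumerate(leaves)}
        for rules in rulesets:
            mask = np.zeros((len(leaves), n_w), dtype=bool)
            for r in rules:
                for d in r:
                    taxon = cohort.taxa[pool.det_taxon[d]]
                    w = pool.window_of(d)
                    rows = [leaf_idx[l] for l in cover[taxon] if l in leaf_idx]
                    if rows:
                        mask[np.ix_(rows, range(w.i0, w.i0 + w.n_basic))] = True
            hits += mask
        return hits

    h_post = hit_matrix(post_rules)
    h_prior = hit_matrix(prior_rules)
    n_post, n_prior = len(post_rules), len(prior_rules)
    bf = np.empty_like(h_post)
    for i in range(bf.shape[0]):
        for j in range(bf.shape[1]):
            po, _, _ = _smoothed_odds(h_post[i, j], n_post - h_post[i, j])
            pr, _, _ = _smoothed_odds(h_prior[i, j], n_prior - h_prior[i, j])
            bf[i, j] = po / pr
    cols = [f"window_{w.t0:g}_{w.t1:g}" for w in pool.basic_windows]
    df = pd.DataFrame(bf, index=leaves, columns=cols)
    if path is not None:
        df.to_csv(f"{path}.csv")
        df.to_json(f"{path}.json", orient="split", indent=1)
    return df


# --- prediction -------------------------------------------------------------


@dataclass
class Prediction:
    subject: str
    probability: float
    call: int
    mode: str


def _subject_detector_truth(pool: DetectorPool, needed, times, abundance):
    """Truth values of the needed detectors for one (possibly new) subject."""
    needed_combos = sorted({int(pool.det_combo[d]) for d in needed})
    stats = {}
    missing = []
    for ci in needed_combos:
        taxon_idx, window, kind = pool.combos[ci]
        try:
            stats[ci] = (
                window_average(times, abundance[taxon_idx], window)
                if kind == AVERAGE
                else window_slope(times, abundance[taxon_idx], window)
            )
        except ValueError:
            missing.append((window.t0, window.t1))
    if missing:
        raise ValueError(
            f"subject lacks required samples in windows {sorted(set(missing))}"
        )
    out = {}
    for d in needed:
        stat = stats[int(pool.det_combo[d])]
        theta = pool.det_threshold[d]
        out[d] = stat > theta if pool.det_above[d] else stat < theta
    return out


def _ruleset_probability(rules, beta0, beta, det_truth, covariates=None, beta_cov=None):
    psi = beta0
    for rule, bk in zip(rules, beta):
        if all(det_truth[d] for d in rule):
            psi += bk
    if covariates is not None and beta_cov is not None and len(beta_cov):
        psi += float(np.dot(covariates, beta_cov))
    return float(_sigmoid(psi))


def predict(
    source, pool: DetectorPool, times, abundance,
    mode: str = "point", subject: str = "subject", covariates=None,
) -> Prediction:
    """Predict the outcome probability for one subject.

    ``source`` is either a point estimate tuple ``(rules, beta0, beta,
    beta_cov)`` (mode "point") or a Trace (mode "ensemble", posterior
    predictive mean over the post-burn-in samples).  ``abundance`` rows must
    follow the pool's taxa.
    """
    times = np.asarray(times, dtype=float)
    abundance = np.asarray(abundance, dtype=float)
    if mode == "point":
        rules, beta0, beta, beta_cov = source
        needed = sorted({d for r in rules for d in r})
        det_truth = _subject_detector_truth(pool, needed, times, abundance)
        p = _ruleset_probability(rules, beta0, beta, det_truth, covariates, beta_cov)
    elif mode == "ensemble":
        post = source.post_burn_in()
        needed = sorted({d for s in post for r in s.rules for d in r})
        det_truth = _subject_detector_truth(pool, needed, times, abundance)
        p = float(np.mean([
            _ruleset_probability(
                s.rules, s.beta0, s.beta, det_truth, covariates, s.beta_cov
            )
            for s in post
        ]))
    else:
        raise ValueError(f"unknown prediction mode {mode!r}")
    return Prediction(subject, p, int(p > 0.5), mode)


# --- cross-validation -------------------------------------------------------


@dataclass
class CrossValidationResult:
    f1_point: float
    f1_ensemble: float
    f1_majority_baseline: float
    folds: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, fold in enumerate(self.folds):
            for pred in fold["predictions"]:
                rows.append({
                    "fold": i, "subject": pred["subject"], "y": pred["y"],
                    "p_point": pred["p_point"], "p_ensemble": pred["p_ensemble"],
                })
        return pd.DataFrame(rows)


def cross_validate(
    cohort, prior: PriorConfig | None = None, pool_params: PoolParams | None = None,
    n_folds: int = 5, seed: int = 0, n_samples: int = 10_000, n_mh: int = 10,
) -> CrossValidationResult:
    """Stratified subject-level cross-validation with pooled F1 at threshold
    0.5; the detector pool (and its thresholds) is rebuilt inside each
    training fold."""
    prior = prior or PriorConfig()
    y = cohort.y
    if n_folds > cohort.n_subjects:
        raise ValueError(f"n_folds={n_folds} exceeds {cohort.n_subjects} subjects")
    if min(np.bincount(y, minlength=2)) < n_folds:
        raise ValueError("each class needs at least n_folds subjects")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = []
    y_true, call_point, call_ens, call_major = [], [], [], []
    for fold_i, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        train_subjects = [cohort.subjects[i] for i in train_idx]
        test_subjects = [cohort.subjects[i] for i in test_idx]
        sub = cohort.subset(train_subjects)
        fold_pool = build_pool(sub, pool_params)
        trace = run_mcmc(
            sub, fold_pool, prior, n_samples=n_samples,
            seed=seed * 1000 + fold_i + 1, n_mh=n_mh,
        )
        point = point_estimate(trace)
        counts = np.bincount(sub.y, minlength=2)
        majority = int(np.argmax(counts))
        preds = []
        for s in test_subjects:
            times = cohort.times[s]
            abundance = cohort.abundance[s]
            cov = (
                cohort.covariates.loc[s].to_numpy(dtype=float)
                if cohort.covariates is not None else None
            )
            p_pt = predict(point, fold_pool, times, abundance, "point", s, cov)
            p_en = predict(trace, fold_pool, times, abundance, "ensemble", s, cov)
            yi = int(cohort.y[cohort.subjects.index(s)])
            preds.append({
                "subject": s, "y": yi,
                "p_point": p_pt.probability, "p_ensemble": p_en.probability,
            })
            y_true.append(yi)
            call_point.append(p_pt.call)
            call_ens.append(p_en.call)
            call_major.append(majority)
        folds.append({"train": train_subjects, "test": test_subjects,
                      "predictions": preds})
    return CrossValidationResult(
        f1_point=float(f1_score(y_true, call_point, zero_division=0)),
        f1_ensemble=float(f1_score(y_true, call_ens, zero_division=0)),
        f1_majority_baseline=float(f1_score(y_true, call_major, zero_division=0)),
        folds=folds,
    )


# --- full summary -----------------------------------------------------------


@dataclass
class SummaryReport:
    point_rules: list  # list of rules, each a list of detector-description dicts
    point_beta0: float
    point_beta: list
    posterior_empty_probability: float
    bayes_factor_empty: float
    bayes_factor_empty_se: float
    clusters: list
    taxon_bayes_factors: dict
    heatmap: pd.DataFrame | None
    positive_label: str
    seed: int

    def to_dict(self) -> dict:
        return {
            "point_estimate": {
                "rules": self.point_rules,
                "beta0": self.point_beta0,
                "beta": list(self.point_beta),
                "baseline_probability": float(_sigmoid(self.point_beta0)),
            },
            "posterior_empty_probability": self.posterior_empty_probability,
            "bayes_factor_empty": self.bayes_factor_empty,
            "bayes_factor_empty_se": self.bayes_factor_empty_se,
            "clusters": [
                {
                    "probability": c["probability"],
                    "contains_point": c["contains_point"],
                    "representative": [list(r) for r in c["representative"]],
                }
                for c in self.clusters
            ],
            "taxon_bayes_factors": self.taxon_bayes_factors,
            "heatmap": None if self.heatmap is None else
            json.loads(self.heatmap.to_json(orient="split")),
            "positive_label": self.positive_label,
            "seed": self.seed,
        }



def summarize(
    trace: Trace, pool: DetectorPool, cohort, prior: PriorConfig,
    overlap_frac: float = 0.5, with_heatmap: bool = True,
    n_prior_sims: int = 100_000,
) -> SummaryReport:
    """Build the full posterior summary from a trace."""
    rules, beta0, beta, _ = point_estimate(trace)
    post = trace.post_burn_in()
    p_empty = sum(1 for s in post if s.is_empty) / len(post)
    bf, se = bayes_factor_empty(trace, prior)
    clusters, det_cluster = cluster_rule_sets(trace, pool, overlap_frac)
    point_key = tuple(sorted(
        tuple(sorted(det_cluster.get(d, d) for d in r)) for r in rules
    ))
    cluster_rows = []
    for c in clusters:
        cluster_rows.append({
            "probability": c["probability"],
            "representative": c["representative"],
            "contains_point": c["key"] == point_key,
        })
    taxon_bfs = {}
    heat = None
    if with_heatmap:
        heat = heatmap_export(
            trace, pool, cohort, prior, n_prior_sims=n_prior_sims
        )
        used_taxa = sorted({
            cohort.taxa[pool.det_taxon[d]]
            for s in post for r in s.rules for d in r
        })
        for t in used_taxa:
            try:
                taxon_bfs[t] = bayes_factor_feature(
                    trace, prior, pool, cohort, taxon=t,
                    n_prior_sims=n_prior_sims,
                )
            except ValueError:
                continue
    positive = next(
        (str(k) for k, v in cohort.label_mapping.items() if v == 1), "1"
    )
    described = [
        [pool.describe(d) for d in r] for r in rules
    ]
    return SummaryReport(
        point_rules=described,
        point_beta0=float(beta0),
        point_beta=[float(b) for b in beta],
        posterior_empty_probability=p_empty,
        bayes_factor_empty=bf,
        bayes_factor_empty_se=se,
        clusters=cluster_rows,
        taxon_bayes_factors=taxon_bfs,
        heatmap=heat,
        positive_label=positive,
        seed=trace.seed,
    )
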