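"""Generative semi-synthetic cohorts for testing the whole pipeline.

Each OTU's latent abundance follows a left-truncated Gaussian random walk
over the sampling grid; case/control status is driven by a time-localized
additive perturbation to one (or two) phylogenetic clades, with per-subject
magnitudes drawn from group-specific log-normal distributions; sequencing
counts arise through a two-stage error model (truncated-normal measurement
noise, then Dirichlet-multinomial reads with concentration alpha).

The generator emits the same four input files the analysis pipeline reads,
plus a ground-truth record of the perturbation, so simulations are
round-trippable through the full tool.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .io import PlacedTree, RawCounts, SampleMap, SubjectInfo

__all__ = [
    "SimConfig",
    "SyntheticCohort",
    "random_coalescent_tree",
    "simulate_latent_trajectories",
    "select_perturbation_targets",
    "apply_perturbation",
    "simulate_counts",
    "generate_cohort",
]


@dataclass
class SimConfig:
    """Simulation scenario parameters.

    Defaults reproduce the one-clade benchmark scenario: 32 subjects (half
    cases), 18 evenly spaced time points on [10, 600] days, one 120-day
    perturbation applied to a random eligible clade (mean relative abundance
    between 0.1% and 20%, at most 30 OTUs), per-subject magnitudes
    log-normal with log-means -3 (cases) and -6 (controls), log-s.d. 1.5,
    and 50,000 Dirichlet-multinomial reads per sample at concentration 286.
    """

    n_subjects: int = 32
    n_timepoints: int = 18
    t_start: float = 10.0
    t_end: float = 600.0
    n_otus: int = 50
    tau2: float = 1e-7  # random-walk process variance per unit time
    theta_noise: float = 0.01  # first-stage measurement noise scale
    alpha: float = 286.0  # Dirichlet-multinomial concentration
    n_reads: int = 50_000
    perturbation_duration: float = 120.0
    n_perturbations: int = 1
    min_clade_abundance: float = 1e-3
    max_clade_abundance: float = 0.2
    max_clade_otus: int = 30
    min_clade_otus: int = 2
    mu_case: float = -3.0
    mu_control: float = -6.0
    sigma_magnitude: float = 1.5
    perturbation_sign: int = 1  # +1 additive increase, -1 decrease
    init_lognormal_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects % 2:
            raise ValueError("n_subjects must be even (equal cases and controls)")
        if self.n_subjects < 2 or self.n_timepoints < 2 or self.n_otus < 3:
            raise ValueError("degenerate scenario size")
        if not self.min_clade_abundance < self.max_clade_abundance:
            raise ValueError("clade abundance eligibility bounds out of order")
        if self.perturbation_duration >= self.t_end - self.t_start:
            raise ValueError("perturbation longer than the study")
        if self.n_perturbations not in (1, 2):
            raise ValueError("n_perturbations must be 1 or 2")


@dataclass
class SyntheticCohort:
    """Simulated inputs plus ground truth."""

    counts: RawCounts
    sample_map: SampleMap
    subjects: SubjectInfo
    tree: PlacedTree
    ground_truth: dict
    trajectories: dict = field(default_factory=dict)  # subject -> (otus, times)

    def write(self, outdir):
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.counts.to_frame().to_csv(outdir / "counts.csv")
        self.sample_map.table.reset_index().to_csv(
            outdir / "sample_metadata.csv", index=False
        )
        rows = [
            {"subject_id": s, "outcome": "case" if y else "control"}
            for s, y in self.subjects.outcomes.items()
        ]
        pd.DataFrame(rows).to_csv(outdir / "subjects.csv", index=False)
        newick = self.tree.tree.as_string(schema="newick", suppress_rooting=True)
        (outdir / "tree.newick").write_text(newick)
        gt = dict(self.ground_truth)
        gt["latent_trajectories"] = {
            s: np.asarray(x).tolist() for s, x in self.trajectories.items()
        }
        (outdir / "ground_truth.json").write_text(json.dumps(gt, indent=1, sort_keys=True))
        return outdir


def random_coalescent_tree(n_otus: int, seed: int) -> PlacedTree:
    """Random Kingman-coalescent topology with OTU-labeled leaves and
    internal nodes labeled deterministically for stable clade ids."""
    taxa = dendropy.TaxonNamespace([f"OTU{i:03d}" for i in range(n_otus)])
    tree = dendropy.simulate.treesim.pure_kingman_tree(
        taxon_namespace=taxa, pop_size=1.0, rng=random.Random(seed)
    )
    idx = 0
    for node in tree.postorder_node_iter():
        if not node.is_leaf():
            node.label = f"clade{idx:03d}"
            idx += 1
    return PlacedTree(tree)


def _truncated_normal(rng, mean, var):
    """Vectorized draw from Normal(mean, var) left-truncated at 0 (proper
    truncation by resampling, not clipping); zero-variance entries pass
    through their (non-negative) mean."""
    mean = np.asarray(mean, dtype=float)
    sd = np.sqrt(np.broadcast_to(np.asarray(var, dtype=float), mean.shape))
    out = np.where(sd > 0, rng.normal(mean, np.where(sd > 0, sd, 1.0)), mean)
    bad = (out < 0) & (sd > 0)
    tries = 0
    while bad.any():
        out[bad] = rng.normal(mean[bad] if mean.shape else mean, sd[bad])
        bad = (out < 0) & (sd > 0)
        tries += 1
        if tries > 1000:
            # pathological truncation (mean << 0): fall back to folded tail
            out[bad] = np.abs(rng.normal(mean[bad], sd[bad]))
            break
    return out


def simulate_latent_trajectories(config: SimConfig, rng, initial=None):
    """Latent abundances x[subject, otu, time] via a truncated Gaussian
    random walk with per-step variance dt * tau2."""
    times = np.linspace(config.t_start, config.t_end, config.n_timepoints)
    if initial is None:
        initial = rng.lognormal(0.0, config.init_lognormal_sigma, config.n_otus)
        initial = initial / initial.sum()
    x = np.empty((config.n_subjects, config.n_otus, config.n_timepoints))
    x[:, :, 0] = np.broadcast_to(initial, (config.n_subjects, config.n_otus))
    for t in range(1, config.n_timepoints):
        dt = times[t] - times[t - 1]
        x[:, :, t] = _truncated_normal(rng, x[:, :, t - 1], dt * config.tau2)
    return times, x, initial


def select_perturbation_targets(tree: PlacedTree, baseline, config: SimConfig, rng):
    """Uniformly pick eligible clade(s): baseline mean relative abundance in
    [min, max] and at most the configured number of member OTUs; two-clade
    scenarios require disjoint OTU sets."""
    otu_ids = tree.leaf_ids
    otu_index = {o: i for i, o in enumerate(otu_ids)}
    leaves_under = tree.leaves_under()
    eligible = []
    for node_id, members in leaves_under.items():
        ab = sum(baseline[otu_index[m]] for m in members)
        if (
            config.min_clade_abundance <= ab <= config.max_clade_abundance
            and config.min_clade_otus <= len(members) <= config.max_clade_otus
        ):
            eligible.append(node_id)
    eligible.sort()
    if not eligible:
        raise ValueError("no clade satisfies the perturbation eligibility bounds")
    if config.n_perturbations == 1:
        return [eligible[int(rng.integers(len(eligible)))]]
    order = rng.permutation(len(eligible))
    first = eligible[order[0]]
    first_set = set(leaves_under[first])
    for j in order[1:]:
        cand = eligible[j]
        if not first_set & set(leaves_under[cand]):
            return [first, cand]
    raise ValueError("no second disjoint eligible clade available")


def apply_perturbation(x, times, member_indices, shares, window, magnitudes):
    """Add per-subject magnitude ``magnitudes[s]`` to the clade's latent
    abundance inside the window, apportioned by the members' baseline
    relative shares; trajectories outside the window are untouched."""
    t0, t1 = window
    in_window = (times >= t0) & (times <= t1)
    x = x.copy()
    add = np.asarray(magnitudes)[:, None, None] * np.asarray(shares)[None, :, None]
    x[:, member_indices, :] = np.where(
        in_window[None, None, :],
        np.maximum(x[:, member_indices, :] + add, 0.0),
        x[:, member_indices, :],
    )
    return x


def simulate_counts(x, config: SimConfig, rng):
    """Two-stage error model: y ~ Normal_+(x, theta x), then Dirichlet-
    multinomial counts with concentration alpha and n_reads per sample."""
    n_subj, n_otus, n_t = x.shape
    counts = np.empty((n_subj, n_otus, n_t), dtype=np.int64)
    for s in range(n_subj):
        for t in range(n_t):
            xv = x[s, :, t]
            y = _truncated_normal(rng, xv, config.theta_noise * xv)
            m = y.sum()
            if m == 0:
                raise ValueError("all-zero latent state; cannot form composition")
            p = y / m
            gam = rng.standard_gamma(np.maximum(config.alpha * p, 0.0))
            if gam.sum() == 0:
                gam = p
            q = gam / gam.sum()
            counts[s, :, t] = rng.multinomial(config.n_reads, q)
    return counts


def generate_cohort(config: SimConfig) -> SyntheticCohort:
    """Run the full generative model; reproducible given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    tree = random_coalescent_tree(config.n_otus, config.seed + 1)
    otu_ids = tree.leaf_ids
    otu_index = {o: i for i, o in enumerate(otu_ids)}
    times, x, baseline = simulate_latent_trajectories(config, rng)
    subjects = [f"S{i:03d}" for i in range(config.n_subjects)]
    half = config.n_subjects // 2
    y = np.array([0] * half + [1] * (config.n_subjects - half))

    clades = select_perturbation_targets(tree, baseline, config, rng)
    leaves_under = tree.leaves_under()
    perturbations = []
    for ci, clade in enumerate(clades):
        members = leaves_under[clade]
        midx = [otu_index[m] for m in members]
        share_raw = baseline[midx]
        shares = share_raw / share_raw.sum()
        w0 = float(rng.uniform(
            config.t_start, config.t_end - config.perturbation_duration
        ))
        window = (w0, w0 + config.perturbation_duration)
        mu = np.where(y == 1, config.mu_case, config.mu_control)
        magnitudes = config.perturbation_sign * np.exp(
            rng.normal(mu, config.sigma_magnitude)
        )
        # two-clade design: controls receive only the first perturbation
        applied = np.ones(config.n_subjects, dtype=bool)
        if config.n_perturbations == 2 and ci == 1:
            applied = y == 1
        eff = np.where(applied, magnitudes, 0.0)
        x = apply_perturbation(x, times, midx, shares, window, eff)
        perturbations.append({
            "clade": clade,
            "members": list(members),
            "window": [window[0], window[1]],
            "magnitudes": {
                s: float(m) for s, m in zip(subjects, eff)
            },
        })

    counts3 = simulate_counts(x, config, rng)
    sample_ids = []
    sample_rows = []
    cols = []
    for si, s in enumerate(subjects):
        for ti, t in enumerate(times):
            sid = f"{s}_T{ti:02d}"
            sample_ids.append(sid)
            sample_rows.append({"sample_id": sid, "subject_id": s, "time": float(t)})
            cols.append(counts3[si, :, ti])
    raw = RawCounts(list(otu_ids), sample_ids, np.column_stack(cols))
    sample_map = SampleMap(
        pd.DataFrame(sample_rows).set_index("sample_id")[["subject_id", "time"]]
    )
    info = SubjectInfo(
        outcomes={s: int(v) for s, v in zip(subjects, y)},
        label_mapping={"control": 0, "case": 1},
    )
    ground_truth = {
        "config": asdict(config),
        "seed": config.seed,
        "times": times.tolist(),
        "outcomes": {s: int(v) for s, v in zip(subjects, y)},
        "perturbations": perturbations,
        "baseline": baseline.tolist(),
        "otu_ids": list(otu_ids),
    }
    trajectories = {s: x[si] for si, s in enumerate(subjects)}
    return SyntheticCohort(raw, sample_map, info, tree, ground_truth, trajectories)
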