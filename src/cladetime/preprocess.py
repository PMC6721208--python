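"""Filtering and aggregation producing the analysis-ready cohort.

The pipeline applies six steps, in order: (1) drop rare OTUs, (2) drop
low-depth samples, (3) trim to the analysis time range, (4) drop sparsely
sampled subjects, then convert to relative abundance and sum abundances up the
phylogeny, (5) drop taxa that never sustain a minimum abundance, and (6)
collapse phylogeny nodes left with a single child.  Leaf fractions per sample
sum to 1 before step 5; afterwards the sums may be smaller because filtered
taxa are removed outright.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import PlacedTree, RawCounts, SampleMap, SubjectInfo

logger = logging.getLogger(__name__)

__all__ = [
    "FilterParams",
    "Cohort",
    "filter_rare_otus",
    "filter_low_depth_samples",
    "trim_time_range",
    "filter_sparse_subjects",
    "to_relative_abundance",
    "aggregate_to_tree",
    "filter_taxa_by_abundance",
    "prune_redundant_nodes",
    "build_cohort",
]


class FilterError(ValueError):
    """Raised when a filtering step empties the dataset."""


@dataclass
class FilterParams:
    """Thresholds for the six preprocessing steps.

    ``n_counts_otu``: minimum total reads for an OTU to be kept.
    ``n_counts_sample``: minimum total reads for a sample to be kept.
    ``t_i, t_f``: analysis time range (default: observed range).
    ``n_w_filter, n_s, n_c``: a subject is kept only if every run of ``n_c``
    consecutive pieces of the ``n_w_filter``-piece partition of the study
    contains at least ``n_s`` of its samples.
    ``a, n_a, n_i``: a taxon is kept if its abundance strictly exceeds ``a``
    in at least ``n_a`` consecutive samples of at least ``n_i`` subjects
    (default ``n_i``: max(4, 10% of subjects)).
    ``taxa_cap``: advisory upper bound on the retained taxon count.
    """

    n_counts_otu: int = 10
    n_counts_sample: int = 5000
    t_i: float | None = None
    t_f: float | None = None
    n_w_filter: int = 10
    n_s: int = 2
    n_c: int = 1
    a: float = 1e-4
    n_a: int = 2
    n_i: int | None = None
    taxa_cap: int = 500

    def __post_init__(self):
        if self.n_counts_otu < 0 or self.n_counts_sample < 0:
            raise ValueError("count thresholds must be non-negative")
        if self.t_i is not None and self.t_f is not None and self.t_i >= self.t_f:
            raise ValueError(f"t_i={self.t_i} must be < t_f={self.t_f}")
        if self.n_w_filter < 1 or self.n_c < 1:
            raise ValueError("n_w_filter and n_c must be >= 1")


@dataclass
class Cohort:
    """Per-subject taxon time series plus outcomes, covariates and taxonomy.

    ``abundance[s]`` is an (n_taxa, n_times) array of relative abundances at
    the (sorted) sample times ``times[s]``; rows follow ``taxa``.  ``parent``
    maps each retained taxon to its nearest retained ancestor (None at roots);
    ``leaves`` lists retained taxa with no retained descendants.
    """

    subjects: list
    y: np.ndarray
    times: dict
    abundance: dict
    taxa: list
    parent: dict
    t_start: float
    t_end: float
    covariates: pd.DataFrame | None = None
    label_mapping: dict = field(default_factory=dict)

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=np.int64)
        self.taxon_index = {t: i for i, t in enumerate(self.taxa)}

    @property
    def n_subjects(self):
        return len(self.subjects)

    @property
    def duration(self):
        return self.t_end - self.t_start

    @property
    def leaves(self):
        has_child = set(p for p in self.parent.values() if p is not None)
        return [t for t in self.taxa if t not in has_child]

    def children(self, taxon):
        return [t for t, p in self.parent.items() if p == taxon]

    def ancestors(self, taxon):
        out = []
        p = self.parent.get(taxon)
        while p is not None:
            out.append(p)
            p = self.parent.get(p)
        return out

    def series(self, subject, taxon):
        """(times, values) for one subject/taxon."""
        return self.times[subject], self.abundance[subject][self.taxon_index[taxon]]

    def subset(self, subjects) -> "Cohort":
        """Restrict to the given subjects (order preserved)."""
        idx = [self.subjects.index(s) for s in subjects]
        return Cohort(
            subjects=list(subjects),
            y=self.y[idx],
            times={s: self.times[s] for s in subjects},
            abundance={s: self.abundance[s] for s in subjects},
            taxa=list(self.taxa),
            parent=dict(self.parent),
            t_start=self.t_start,
            t_end=self.t_end,
            covariates=(
                self.covariates.loc[list(subjects)] if self.covariates is not None else None
            ),
            label_mapping=dict(self.label_mapping),
        )


def filter_rare_otus(raw: RawCounts, n_counts_otu: int) -> RawCounts:
    """Step 1: drop OTUs with total counts below ``n_counts_otu`` (strict)."""
    totals = raw.counts.sum(axis=1)
    keep = totals >= n_counts_otu
    if not keep.any():
        raise FilterError(
            f"all {len(raw.otu_ids)} OTUs have total counts < {n_counts_otu}"
        )
    dropped = [o for o, k in zip(raw.otu_ids, keep) if not k]
    if dropped:
        logger.info("step 1: dropped %d rare OTUs: %s", len(dropped), dropped)
    return RawCounts(
        [o for o, k in zip(raw.otu_ids, keep) if k], list(raw.sample_ids),
        raw.counts[keep],
    )


def filter_low_depth_samples(raw: RawCounts, n_counts_sample: int) -> RawCounts:
    """Step 2: drop samples with remaining total counts below the threshold."""
    totals = raw.counts.sum(axis=0)
    keep = totals >= n_counts_sample
    if not keep.any():
        raise FilterError(
            f"all samples have total counts < {n_counts_sample}"
        )
    dropped = [s for s, k in zip(raw.sample_ids, keep) if not k]
    if dropped:
        logger.info("step 2: dropped %d low-depth samples: %s", len(dropped), dropped)
    return RawCounts(
        list(raw.otu_ids), [s for s, k in zip(raw.sample_ids, keep) if k],
        raw.counts[:, keep],
    )


def trim_time_range(
    raw: RawCounts, samples: SampleMap, t_i=None, t_f=None
) -> RawCounts:
    """Step 3: keep only samples with time in [t_i, t_f]."""
    times = np.array([samples.time_of(s) for s in raw.sample_ids])
    lo = times.min() if t_i is None else float(t_i)
    hi = times.max() if t_f is None else float(t_f)
    if lo >= hi:
        raise ValueError(f"t_i={lo} must be < t_f={hi}")
    keep = (times >= lo) & (times <= hi)
    if not keep.any():
        raise FilterError(f"no samples inside time range [{lo}, {hi}]")
    dropped = [s for s, k in zip(raw.sample_ids, keep) if not k]
    if dropped:
        logger.info("step 3: dropped %d out-of-range samples", len(dropped))
    return RawCounts(
        list(raw.otu_ids), [s for s, k in zip(raw.sample_ids, keep) if k],
        raw.counts[:, keep],
    )


def filter_sparse_subjects(
    raw: RawCounts, samples: SampleMap, n_w_filter=10, n_s=2, n_c=1,
    t_start=None, t_end=None,
) -> RawCounts:
    """Step 4: keep subjects with >= n_s samples in every run of n_c
    consecutive pieces of the n_w_filter-piece partition of the study."""
    times = np.array([samples.time_of(s) for s in raw.sample_ids])
    subj = np.array([samples.subject_of(s) for s in raw.sample_ids])
    lo = times.min() if t_start is None else float(t_start)
    hi = times.max() if t_end is None else float(t_end)
    edges = np.linspace(lo, hi, n_w_filter + 1)
    diagnostics = {}
    keep_subjects = set()
    for s in pd.unique(subj):
        ts = times[subj == s]
        # piece membership: [edge_i, edge_{i+1}), last piece closed
        piece = np.clip(np.searchsorted(edges, ts, side="right") - 1, 0, n_w_filter - 1)
        per_piece = np.bincount(piece, minlength=n_w_filter)
        runs = np.array([
            per_piece[i : i + n_c].sum() for i in range(n_w_filter - n_c + 1)
        ])
        if (runs >= n_s).all():
            keep_subjects.add(s)
        else:
            diagnostics[s] = per_piece.tolist()
    if not keep_subjects:
        raise FilterError(
            f"all subjects too sparsely sampled; per-piece sample counts: {diagnostics}"
        )
    if diagnostics:
        logger.info("step 4: dropped subjects %s", sorted(diagnostics))
    keep = np.array([samples.subject_of(s) in keep_subjects for s in raw.sample_ids])
    return RawCounts(
        list(raw.otu_ids), [s for s, k in zip(raw.sample_ids, keep) if k],
        raw.counts[:, keep],
    )


def to_relative_abundance(raw: RawCounts) -> pd.DataFrame:
    """Convert counts to per-sample fractions (columns sum to 1)."""
    totals = raw.counts.sum(axis=0)
    if (totals == 0).any():
        bad = [s for s, t in zip(raw.sample_ids, totals) if t == 0]
        raise FilterError(f"zero-total samples: {bad}")
    return pd.DataFrame(
        raw.counts / totals[None, :].astype(float),
        index=raw.otu_ids, columns=raw.sample_ids,
    )


def aggregate_to_tree(fractions: pd.DataFrame, tree: PlacedTree) -> pd.DataFrame:
    """Sum leaf fractions bottom-up to every internal node of the tree.

    Tree leaves absent from the table contribute zero; table OTUs absent from
    the tree are an error.
    """
    leaf_ids = set(tree.leaf_ids)
    missing = sorted(set(fractions.index) - leaf_ids)
    if missing:
        raise FilterError(f"OTUs not present as tree leaves: {missing}")
    rows = {}
    for node in tree.tree.postorder_node_iter():
        nid = node.cladetime_id
        if node.is_leaf():
            if nid in fractions.index:
                rows[nid] = fractions.loc[nid].to_numpy(dtype=float)
            else:
                rows[nid] = np.zeros(fractions.shape[1])
        else:
            rows[nid] = sum(rows[ch.cladetime_id] for ch in node.child_nodes())
    order = [n.cladetime_id for n in tree.tree.postorder_node_iter()]
    return pd.DataFrame(
        np.vstack([rows[n] for n in order]), index=order, columns=fractions.columns
    )


def _taxon_passes(values: np.ndarray, a: float, n_a: int) -> bool:
    # strictly exceeds `a` in at least n_a consecutive time-ordered samples
    if n_a <= 0:
        return True
    run = 0
    for v in values:
        run = run + 1 if v > a else 0
        if run >= n_a:
            return True
    return False


def filter_taxa_by_abundance(
    table: pd.DataFrame, samples: SampleMap, a=1e-4, n_a=2, n_i=None
) -> pd.DataFrame:
    """Step 5: keep taxa exceeding abundance ``a`` in >= ``n_a`` consecutive
    samples (time order within a subject) in >= ``n_i`` subjects."""
    subj = np.array([samples.subject_of(s) for s in table.columns])
    times = np.array([samples.time_of(s) for s in table.columns])
    subjects = pd.unique(subj)
    if n_i is None:
        n_i = max(4, int(np.ceil(0.1 * len(subjects))))
    order = {
        s: np.nonzero(subj == s)[0][np.argsort(times[subj == s], kind="stable")]
        for s in subjects
    }
    values = table.to_numpy(dtype=float)
    keep = []
    for r in range(values.shape[0]):
        hits = sum(
            _taxon_passes(values[r, order[s]], a, n_a) for s in subjects
        )
        keep.append(hits >= n_i)
    dropped = [t for t, k in zip(table.index, keep) if not k]
    if dropped:
        logger.info("step 5: dropped %d low-abundance taxa", len(dropped))
    return table.loc[keep]


def prune_redundant_nodes(
    table: pd.DataFrame, tree: PlacedTree, taxa_cap: int = 500
) -> tuple[pd.DataFrame, dict]:
    """Step 6: drop internal taxa with exactly one remaining child, repeatedly,
    and return the filtered table plus the retained-taxon parent map."""
    retained = set(table.index)
    full_parent = tree.parent_map()

    def nearest_retained_parent(taxon):
        p = full_parent.get(taxon)
        while p is not None and p not in retained:
            p = full_parent.get(p)
        return p

    while True:
        parent = {t: nearest_retained_parent(t) for t in retained}
        n_children = {}
        for t, p in parent.items():
            if p is not None:
                n_children[p] = n_children.get(p, 0) + 1
        unifilar = {t for t in retained if n_children.get(t, 0) == 1}
        if not unifilar:
            break
        logger.info("step 6: removing single-child taxa %s", sorted(unifilar))
        retained -= unifilar
    parent = {t: nearest_retained_parent(t) for t in retained}
    if len(retained) > taxa_cap:
        warnings.warn(
            f"{len(retained)} taxa retained, above the recommended cap of "
            f"{taxa_cap}; consider more stringent abundance filtering",
            stacklevel=2,
        )
    kept_order = [t for t in table.index if t in retained]
    return table.loc[kept_order], {t: parent[t] for t in kept_order}


def build_cohort(
    raw: RawCounts,
    samples: SampleMap,
    subjects: SubjectInfo,
    tree: PlacedTree,
    params: FilterParams | None = None,
) -> Cohort:
    """Run the full preprocessing pipeline and assemble the cohort."""
    params = params or FilterParams()
    missing_meta = sorted(set(raw.sample_ids) - set(samples.sample_ids))
    if missing_meta:
        raise FilterError(f"samples without metadata: {missing_meta}")
    raw = filter_rare_otus(raw, params.n_counts_otu)
    raw = filter_low_depth_samples(raw, params.n_counts_sample)
    raw = trim_time_range(raw, samples, params.t_i, params.t_f)
    times_all = np.array([samples.time_of(s) for s in raw.sample_ids])
    t_start = times_all.min() if params.t_i is None else params.t_i
    t_end = times_all.max() if params.t_f is None else params.t_f
    raw = filter_sparse_subjects(
        raw, samples, params.n_w_filter, params.n_s, params.n_c, t_start, t_end
    )
    sample_subjects = pd.unique(
        np.array([samples.subject_of(s) for s in raw.sample_ids])
    )
    no_outcome = sorted(set(sample_subjects) - set(subjects.outcomes))
    if no_outcome:
        raise FilterError(f"subjects with samples but no outcome: {no_outcome}")
    fractions = to_relative_abundance(raw)
    table = aggregate_to_tree(fractions, tree)
    table = filter_taxa_by_abundance(table, samples, params.a, params.n_a, params.n_i)
    table, parent = prune_redundant_nodes(table, tree, params.taxa_cap)
    if table.empty:
        raise FilterError("no taxa survived abundance filtering")

    subj_list = sorted(sample_subjects)
    times = {}
    abundance = {}
    cols = np.array(table.columns)
    col_subj = np.array([samples.subject_of(s) for s in cols])
    col_time = np.array([samples.time_of(s) for s in cols])
    values = table.to_numpy(dtype=float)
    for s in subj_list:
        mask = col_subj == s
        order = np.argsort(col_time[mask], kind="stable")
        times[s] = col_time[mask][order]
        abundance[s] = values[:, mask][:, order]
    y = np.array([subjects.outcomes[s] for s in subj_list])
    cov = None
    if subjects.covariates is not None:
        cov = subjects.covariates.loc[subj_list]
    levels = set(y.tolist())
    if len(levels) != 2:
        raise FilterError(
            f"cohort must contain both outcome classes after filtering, got {levels}"
        )
    return Cohort(
        subjects=subj_list,
        y=y,
        times=times,
        abundance=abundance,
        taxa=list(table.index),
        parent=parent,
        t_start=float(t_start),
        t_end=float(t_end),
        covariates=cov,
        label_mapping=dict(subjects.label_mapping),
    )
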