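"""Readers and writers for the external file formats.

The pipeline consumes four inputs: an OTU x sample count table (CSV), sample
metadata mapping each sample to a subject and a study time (CSV), a subject
table with the binary outcome and optional static covariates (CSV), and a
phylogeny given either as pplacer-style jplace placements or as a plain newick
tree whose leaves are the OTUs.
"""

from __future__ import annotations

import csv
import json
import re
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "RawCounts",
    "SampleMap",
    "SubjectInfo",
    "PlacedTree",
    "read_counts_table",
    "read_sample_metadata",
    "read_subject_table",
    "read_jplace",
    "read_newick_tree",
    "write_report",
]


class FormatError(ValueError):
    """Raised when an input file fails parsing or validation."""


@dataclass
class RawCounts:
    """Integer OTU x sample count matrix with identifier axes."""

    otu_ids: list
    sample_ids: list
    counts: np.ndarray  # shape (n_otus, n_samples), non-negative integers

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise FormatError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.otu_ids)} OTUs x {len(self.sample_ids)} samples"
            )
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise FormatError("duplicate OTU ids in counts table")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids in counts table")
        if (self.counts < 0).any():
            raise FormatError("negative values in counts table")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.otu_ids, columns=self.sample_ids)


@dataclass
class SampleMap:
    """sample_id -> (subject_id, time)."""

    table: pd.DataFrame  # index sample_id, columns subject_id (str), time (float)

    @property
    def sample_ids(self):
        return list(self.table.index)

    def subject_of(self, sample_id):
        return self.table.loc[sample_id, "subject_id"]

    def time_of(self, sample_id) -> float:
        return float(self.table.loc[sample_id, "time"])

    def __len__(self):
        return len(self.table)


@dataclass
class SubjectInfo:
    """subject_id -> binary outcome, plus optional static covariates."""

    outcomes: dict  # subject_id -> 0/1
    label_mapping: dict  # original label -> 0/1
    covariates: pd.DataFrame | None = None  # indexed by subject_id
    covariate_mappings: dict = field(default_factory=dict)


@dataclass
class PlacedTree:
    """Rooted tree whose leaves include every study OTU.

    ``node_ids`` assigns a stable identifier to every node: leaf labels for
    leaves, and either the newick label or a deterministic postorder id for
    internal nodes.  For jplace input, each query OTU has been grafted at its
    single best placement edge.
    """

    tree: dendropy.Tree
    placements: dict = field(default_factory=dict)  # otu -> best edge_num

    def __post_init__(self):
        self._assign_node_ids()

    def _assign_node_ids(self):
        seen = set()
        counter = 0
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                label = node.taxon.label if node.taxon else node.label
                if label is None:
                    raise FormatError("tree contains an unlabeled leaf")
                node_id = str(label)
            elif node.label:
                node_id = str(node.label)
            else:
                node_id = f"node{counter}"
            while node_id in seen:
                counter += 1
                node_id = f"node{counter}"
            seen.add(node_id)
            node.cladetime_id = node_id
            counter += 1

    @property
    def leaf_ids(self):
        return [n.cladetime_id for n in self.tree.leaf_node_iter()]

    def node_by_id(self, node_id):
        for node in self.tree.postorder_node_iter():
            if node.cladetime_id == node_id:
                return node
        raise KeyError(node_id)

    def parent_map(self) -> dict:
        """node id -> parent node id (None for the root)."""
        out = {}
        for node in self.tree.preorder_node_iter():
            out[node.cladetime_id] = (
                node.parent_node.cladetime_id if node.parent_node else None
            )
        return out

    def leaves_under(self) -> dict:
        """node id -> list of descendant leaf ids (leaves map to themselves)."""
        out = {}
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                out[node.cladetime_id] = [node.cladetime_id]
            else:
                leaves = []
                for ch in node.child_nodes():
                    leaves.extend(out[ch.cladetime_id])
                out[node.cladetime_id] = leaves
        return out


def _read_csv_rows(path):
    with open(path, newline="", encoding="utf-8") as fh:
        return list(csv.reader(fh))


def read_counts_table(path) -> RawCounts:
    """Read an OTU x sample CSV (first column OTU ids, header sample ids)."""
    rows = _read_csv_rows(path)
    if not rows or len(rows[0]) < 2:
        raise FormatError(f"{path}: expected a header row with sample ids")
    sample_ids = [c.strip() for c in rows[0][1:]]
    otu_ids = []
    data = np.zeros((len(rows) - 1, len(sample_ids)), dtype=np.int64)
    for i, row in enumerate(rows[1:], start=1):
        if len(row) != len(sample_ids) + 1:
            raise FormatError(f"{path}: row {i + 1} has {len(row)} fields, "
                              f"expected {len(sample_ids) + 1}")
        otu_ids.append(row[0].strip())
        for j, cell in enumerate(row[1:]):
            try:
                value = float(cell)
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric cell {cell!r} at OTU {row[0]!r}, "
                    f"sample {sample_ids[j]!r}"
                ) from None
            if value != int(value):
                raise FormatError(
                    f"{path}: non-integer count {cell!r} at OTU {row[0]!r}, "
                    f"sample {sample_ids[j]!r}"
                )
            data[i - 1, j] = int(value)
    return RawCounts(otu_ids, sample_ids, data)


def read_sample_metadata(path, counts: RawCounts | None = None) -> SampleMap:
    """Read sample metadata CSV with columns sample_id, subject_id, time."""
    df = pd.read_csv(path, dtype={"sample_id": str, "subject_id": str})
    required = {"sample_id", "subject_id", "time"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path}: missing columns {sorted(required - set(df.columns))}"
        )
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"{path}: duplicate sample ids {dups}")
    times = pd.to_numeric(df["time"], errors="coerce")
    if times.isna().any():
        bad = df.loc[times.isna(), "sample_id"].tolist()
        raise FormatError(f"{path}: non-numeric time for samples {bad}")
    if not np.isfinite(times).all():
        raise FormatError(f"{path}: non-finite times present")
    df = df.assign(time=times).set_index("sample_id")[["subject_id", "time"]]
    if counts is not None:
        missing = sorted(set(counts.sample_ids) - set(df.index))
        if missing:
            raise FormatError(
                f"{path}: samples present in counts but missing here: {missing}"
            )
    return SampleMap(df)


def read_subject_table(path, positive_label=None) -> SubjectInfo:
    """Read subject CSV with columns subject_id, outcome, optional covariates.

    Outcomes are coerced to {0, 1}; by default the lexicographically larger
    label maps to 1, overridable via ``positive_label``.  Two-level string
    covariates are recoded as binary, numeric covariates kept as floats.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    if "subject_id" not in df.columns or "outcome" not in df.columns:
        raise FormatError(f"{path}: need columns subject_id and outcome")
    if df["subject_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate subject ids")
    levels = sorted(df["outcome"].astype(str).unique())
    if len(levels) != 2:
        raise FormatError(
            f"{path}: outcome must have exactly two levels, found {levels}"
        )
    if positive_label is not None:
        positive_label = str(positive_label)
        if positive_label not in levels:
            raise FormatError(
                f"{path}: positive_label {positive_label!r} not among {levels}"
            )
    else:
        positive_label = levels[1]
    mapping = {lev: int(lev == positive_label) for lev in levels}
    outcomes = {
        row.subject_id: mapping[str(row.outcome)] for row in df.itertuples()
    }
    cov_cols = [c for c in df.columns if c not in ("subject_id", "outcome")]
    covariates = None
    cov_mappings = {}
    if cov_cols:
        cov = df.set_index("subject_id")[cov_cols].copy()
        for col in cov_cols:
            numeric = pd.to_numeric(cov[col], errors="coerce")
            if not numeric.isna().any():
                cov[col] = numeric.astype(float)
                continue
            lv = sorted(cov[col].astype(str).unique())
            if len(lv) != 2:
                raise FormatError(
                    f"{path}: covariate {col!r} is non-numeric with "
                    f"{len(lv)} levels; only binary string covariates are supported"
                )
            cov_mappings[col] = {lv[0]: 0.0, lv[1]: 1.0}
            cov[col] = cov[col].astype(str).map(cov_mappings[col])
        covariates = cov
    return SubjectInfo(outcomes, mapping, covariates, cov_mappings)


# --- jplace ----------------------------------------------------------------

_EDGE_AFTER_LEN = re.compile(r"(:[0-9eE.+\-]+)\{(\d+)\}")
_EDGE_BARE = re.compile(r"\{(\d+)\}")
_EDGE_TAG = re.compile(r"@@edge(\d+)@@")


def _parse_edge_numbered_newick(newick: str) -> tuple[dendropy.Tree, dict]:
    """Parse a pplacer edge-numbered newick; return (tree, edge_num -> node)."""
    # move each {n} edge tag in front of the branch length, as a label suffix
    s = _EDGE_AFTER_LEN.sub(lambda m: f"@@edge{m.group(2)}@@{m.group(1)}", newick)
    s = _EDGE_BARE.sub(lambda m: f"@@edge{m.group(1)}@@", s)
    tree = dendropy.Tree.get(
        data=s,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    edge_map = {}
    for node in tree.postorder_node_iter():
        label = node.taxon.label if node.is_leaf() and node.taxon else node.label
        if label is None:
            continue
        m = _EDGE_TAG.search(label)
        if m:
            edge_map[int(m.group(1))] = node
            clean = _EDGE_TAG.sub("", label)
            if node.is_leaf() and node.taxon:
                node.taxon.label = clean
            else:
                node.label = clean or None
    return tree, edge_map


def read_jplace(path) -> PlacedTree:
    """Read jplace (pplacer dialect, version 3) and graft each query OTU as a
    leaf at its highest like_weight_ratio placement edge (ties broken by the
    lowest edge number); branch lengths are preserved by splitting the edge."""
    with open(path, encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: malformed JSON ({exc})") from None
    for key in ("tree", "placements", "fields"):
        if key not in doc:
            raise FormatError(f"{path}: jplace document lacks {key!r} key")
    fields = doc["fields"]
    try:
        i_edge = fields.index("edge_num")
        i_lwr = fields.index("like_weight_ratio")
    except ValueError:
        raise FormatError(
            f"{path}: jplace fields must include edge_num and like_weight_ratio"
        ) from None
    i_pendant = fields.index("pendant_length") if "pendant_length" in fields else None

    tree, edge_map = _parse_edge_numbered_newick(doc["tree"])
    placements = {}
    for rec in doc["placements"]:
        if "n" in rec:
            names = list(rec["n"])
        elif "nm" in rec:
            names = [nm[0] for nm in rec["nm"]]
        else:
            raise FormatError(f"{path}: placement record without names")
        rows = rec["p"]
        best = max(rows, key=lambda r: (r[i_lwr], -r[i_edge]))
        edge_num = int(best[i_edge])
        if edge_num not in edge_map:
            raise FormatError(
                f"{path}: placement references unknown edge number {edge_num}"
            )
        pendant = float(best[i_pendant]) if i_pendant is not None else 0.0
        for name in names:
            child = edge_map[edge_num]
            parent = child.parent_node
            blen = child.edge.length or 0.0
            if parent is None:
                # placement on the root edge: attach directly under the root
                attach = child
            else:
                attach = dendropy.Node()
                parent.remove_child(child)
                parent.add_child(attach)
                attach.edge.length = blen / 2.0
                attach.add_child(child)
                child.edge.length = blen / 2.0
                # subsequent placements on this edge split the lower half
                edge_map[edge_num] = child
            leaf = dendropy.Node()
            taxon = dendropy.Taxon(label=str(name))
            tree.taxon_namespace.add_taxon(taxon)
            leaf.taxon = taxon
            leaf.edge.length = pendant
            attach.add_child(leaf)
            placements[str(name)] = edge_num
    return PlacedTree(tree, placements)


def read_newick_tree(path) -> PlacedTree:
    """Read a plain newick tree whose leaves are the study OTUs."""
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        if "Duplicate taxon labels" in str(exc):
            raise FormatError(f"{path}: duplicate leaf labels ({exc})") from None
        raise FormatError(f"{path}: unreadable newick ({exc})") from None
    labels = [
        (n.taxon.label if n.taxon else n.label) for n in tree.leaf_node_iter()
    ]
    if any(lbl is None for lbl in labels):
        raise FormatError(f"{path}: tree contains unlabeled leaves")
    if len(set(labels)) != len(labels):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise FormatError(f"{path}: duplicate leaf labels {dup}")
    if len(labels) == 1:
        warnings.warn(f"{path}: tree has a single leaf", stacklevel=2)
    return PlacedTree(tree)


# --- report ----------------------------------------------------------------


def _render_detector_sentence(det: dict) -> str:
    kind = "average abundance" if det["kind"] == "average" else "slope of the abundance"
    return (
        f"between time {det['t0']:g} and time {det['t1']:g}, "
        f"the {kind} of {det['taxon']} is {det['direction']} {det['threshold']:.4g}"
    )


def write_report(summary, path) -> None:
    """Write a plain-text rule-set report plus a JSON sidecar (``path`` + .json).

    ``summary`` is a SummaryReport from :mod:`cladetime.summaries`.
    """
    lines = []
    point = summary.point_rules
    if not point:
        lines.append("Point estimate: the empty rule set (no rules selected).")
    else:
        lines.append(f"Point estimate: rule set with {len(point)} rule(s).")
        for rule, beta_k in zip(point, summary.point_beta):
            conds = " and ".join(
                "If, " + _render_detector_sentence(d) if i == 0
                else _render_detector_sentence(d)
                for i, d in enumerate(rule)
            )
            odds = float(np.exp(beta_k))
            effect = "increase" if odds >= 1 else "decrease"
            factor = odds if odds >= 1 else 1.0 / odds
            lines.append(
                f"{conds}, the odds of {summary.positive_label!r} "
                f"{effect} by a factor of {factor:.3g}."
            )
    baseline = 1.0 / (1.0 + np.exp(-summary.point_beta0))
    lines.append(
        f"The baseline probability of {summary.positive_label!r} is "
        f"{100.0 * baseline:.1f}%."
    )
    lines.append("")
    lines.append(
        f"Posterior probability of the empty rule set: "
        f"{summary.posterior_empty_probability:.3f}"
    )
    lines.append(
        f"Bayes factor for the empty rule set: {summary.bayes_factor_empty:.3g} "
        f"(MC s.e. {summary.bayes_factor_empty_se:.2g})"
    )
    shown = [c for c in summary.clusters if c["probability"] >= 0.01][:10]
    for i, cl in enumerate(shown):
        star = " (contains the point estimate)" if cl["contains_point"] else ""
        lines.append(
            f"Cluster {i + 1}: posterior probability {cl['probability']:.3f}{star}"
        )
    hidden = len(summary.clusters) - len(shown)
    if hidden > 0:
        lines.append(f"({hidden} further clusters below probability 0.01)")
    text = "\n".join(lines) + "\n"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(text)
    with open(f"{path}.json", "w", encoding="utf-8") as fh:
        json.dump(summary.to_dict(), fh, indent=1, sort_keys=True)
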