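"""Phylogeny-aware gene-loss statistics.

Covers the comparative half of the toolkit: four-way reclassification of
per-species gene status from assembly evidence, inference of loss branches
from loss-of-function (LoF) mutations shared across species, counting of
independent losses and intact branches per branch category (e.g. diet),
contingency tests, the sequential branch-drawing loss simulation, and the
shared-missing-gene simulation used for assembly-completeness assessment.

A loss branch is the branch above the most recent common ancestor of a
maximal clade whose tips are all non-functional and share at least one
identical LoF mutation; a non-functional tip sharing no mutation with its
relatives gets a loss on its own terminal branch. Independent losses are
loss branches with no loss branch among their ancestors.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
from scipy import stats

__all__ = [
    "Phylo",
    "GeneEvidence",
    "LossInference",
    "SimulationResult",
    "reclassify_gene_status",
    "infer_loss_branches",
    "count_losses_by_category",
    "contingency_tests",
    "simulate_random_losses",
    "simulate_shared_missing",
]


class Phylo:
    """Rooted tree with branch lengths and per-branch annotations.

    Node 0 is the root. Every non-root node identifies the branch above it;
    branches optionally carry a category label (e.g. carnivore / herbivore /
    omnivore) and a gene state. The root edge is excluded from the branch
    universe.
    """

    def __init__(
        self,
        parent: list[int],
        length: list[float],
        labels: list[str],
    ):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.length = np.asarray(length, dtype=float)
        self.labels = list(labels)
        n = len(self.parent)
        if n == 0 or self.parent[0] != -1 or np.sum(self.parent == -1) != 1:
            raise ValueError("tree must have exactly one root at index 0")
        if np.any(self.length < 0):
            raise ValueError("branch lengths must be >= 0")
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i in range(1, n):
            self.children[self.parent[i]].append(i)
        self.is_tip = np.array([len(c) == 0 for c in self.children])
        tips = [self.labels[i] for i in np.flatnonzero(self.is_tip)]
        if len(set(tips)) != len(tips):
            raise ValueError("tip labels must be unique")
        self._index = {}
        for i, lab in enumerate(self.labels):
            self._index.setdefault(lab, i)
        self.category: list[str | None] = [None] * n
        self.gene_state: list[str | None] = [None] * n
        self._descendants: list[np.ndarray] | None = None

    # --- construction --------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "Phylo":
        try:
            tree = dendropy.Tree.get(data=newick, schema="newick")
        except Exception as exc:  # dendropy's reader errors vary by cause
            raise ValueError(f"invalid newick (tip labels must be unique): {exc}")
        return cls._from_dendropy(tree)

    @classmethod
    def from_file(cls, path: str | Path) -> "Phylo":
        tree = dendropy.Tree.get(path=str(path), schema="newick")
        return cls._from_dendropy(tree)

    @classmethod
    def _from_dendropy(cls, tree: dendropy.Tree) -> "Phylo":
        nodes = list(tree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent, length, labels = [], [], []
        auto = 0
        for i, nd in enumerate(nodes):
            parent.append(-1 if nd.parent_node is None else index[id(nd.parent_node)])
            length.append(nd.edge.length if nd.edge.length is not None else 1.0)
            if nd.taxon is not None:
                labels.append(nd.taxon.label.replace(" ", "_"))
            elif nd.label:
                labels.append(nd.label)
            else:
                labels.append(f"node{auto}")
                auto += 1
        return cls(parent, length, labels)

    def to_newick(self) -> str:
        def render(i: int) -> str:
            if self.is_tip[i]:
                core = self.labels[i]
            else:
                core = "(" + ",".join(render(c) for c in self.children[i]) + ")"
                core += self.labels[i]
            if self.parent[i] >= 0:
                core += f":{self.length[i]:g}"
            return core

        return render(0) + ";"

    # --- structure queries ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.parent)

    @property
    def n_tips(self) -> int:
        return int(self.is_tip.sum())

    @property
    def branches(self) -> np.ndarray:
        """Non-root node indices (each names the branch above it)."""
        return np.arange(1, len(self.parent))

    @property
    def tip_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_tip)

    def index_of(self, label: str) -> int:
        if label not in self._index:
            raise KeyError(f"no node labelled {label!r}")
        return self._index[label]

    def descendants(self, i: int) -> np.ndarray:
        """All strict descendants of node i (cached, preorder)."""
        if self._descendants is None:
            self._descendants = [None] * len(self.parent)  # type: ignore
            for j in range(len(self.parent) - 1, -1, -1):
                acc: list[int] = []
                for c in self.children[j]:
                    acc.append(c)
                    acc.extend(self._descendants[c])  # type: ignore
                self._descendants[j] = np.array(acc, dtype=np.int64)  # type: ignore
        return self._descendants[i]  # type: ignore

    def ancestors(self, i: int) -> list[int]:
        out = []
        while self.parent[i] >= 0:
            i = self.parent[i]
            out.append(i)
        return out

    def tips_below(self, i: int) -> list[int]:
        if self.is_tip[i]:
            return [i]
        return [d for d in self.descendants(i) if self.is_tip[d]]

    def depths(self) -> np.ndarray:
        """Sum of branch lengths from the root to every node."""
        d = np.zeros(len(self.parent))
        for i in range(1, len(self.parent)):
            d[i] = d[self.parent[i]] + self.length[i]
        return d

    # --- annotations ---------------------------------------------------------

    def set_categories(self, mapping: dict[str, str], tips_only: bool = False) -> None:
        for lab, cat in mapping.items():
            self.category[self.index_of(lab)] = cat
        if tips_only:
            return

    def set_gene_states(self, mapping: dict[str, str]) -> None:
        for lab, st in mapping.items():
            self.gene_state[self.index_of(lab)] = st


# --- four-way status reclassification ---------------------------------------


@dataclass
class GeneEvidence:
    """Assembly-level evidence for one gene in one species."""

    assembly_status: str  # miner status, or "absent"
    lof_set: set[str] = field(default_factory=set)
    sibling_assembly_statuses: list[str] = field(default_factory=list)
    sibling_lof_sets: list[set[str]] = field(default_factory=list)
    relative_lof_sets: list[set[str]] = field(default_factory=list)
    fragments: list[tuple[int, int]] = field(default_factory=list)
    ref_codon_len: int | None = None
    flanking_genes_found_same_scaffold: bool | None = None

    def __post_init__(self):
        if self.assembly_status == "complete" and self.lof_set:
            raise ValueError("a complete gene cannot carry LoF mutations")


def _lof_position(key: str) -> int:
    return int(key.rsplit("@", 1)[1])


def _fragments_cover(fragments: list[tuple[int, int]], ref_len: int) -> bool:
    if not fragments:
        return False
    merged_end = 0
    for s, e in sorted(fragments):
        if s > merged_end + 1:
            return False
        merged_end = max(merged_end, e)
    return merged_end >= ref_len and min(s for s, _ in fragments) <= 1


def reclassify_gene_status(
    evidence: GeneEvidence, distance_codons: int = 50
) -> str:
    """Four-way gene status from assembly evidence.

    complete: found complete, or fragments merge into a full CDS, or a
    sibling assembly of the same species has it complete. high-confidence
    loss: pseudogene with two LoF mutations at least ``distance_codons``
    apart, or a LoF corroborated by a sibling assembly or shared with a
    close relative, or gene absent with both flanking genes on one scaffold.
    low-confidence loss: a single uncorroborated LoF, or absent with the
    flanking genes missing or scattered. Everything else (unresolved edge /
    truncated / ambiguous) is undetermined.
    """
    ev = evidence
    if ev.assembly_status == "complete":
        return "complete"
    if "complete" in ev.sibling_assembly_statuses:
        return "complete"
    if ev.ref_codon_len and _fragments_cover(ev.fragments, ev.ref_codon_len):
        return "complete"
    if ev.assembly_status == "pseudogene":
        positions = sorted(_lof_position(k) for k in ev.lof_set)
        distant = any(
            b - a >= distance_codons
            for a, b in itertools.combinations(positions, 2)
        )
        corroborated = any(
            ev.lof_set & s for s in ev.sibling_lof_sets
        ) or any(ev.lof_set & s for s in ev.relative_lof_sets)
        if (len(positions) >= 2 and distant) or corroborated:
            return "high_confidence_loss"
        return "low_confidence_loss"
    if ev.assembly_status in ("absent", "missing"):
        if ev.flanking_genes_found_same_scaffold:
            return "high_confidence_loss"
        return "low_confidence_loss"
    return "undetermined"


# --- loss-branch inference ---------------------------------------------------


@dataclass
class LossInference:
    """Independent loss branches with their supporting shared LoF keys."""

    loss_branches: list[str]  # node labels (branch above each node)
    support: dict[str, set[str]]
    independent_count: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.loss_branches)) != len(self.loss_branches):
            raise ValueError("duplicate loss branches")


def infer_loss_branches(
    tree: Phylo, per_tip_lof_sets: dict[str, set[str]]
) -> LossInference:
    """Place losses on the branches above maximal shared-LoF clades.

    A tip is non-functional when its LoF set is non-empty. For each maximal
    clade whose tips are all non-functional and share at least one identical
    LoF key, one loss is placed on the branch above the clade's MRCA;
    non-functional tips sharing no mutation with their relatives get
    terminal-branch losses. The output contains no nested loss branches.
    """
    for i in tree.tip_indices:
        if tree.labels[i] not in per_tip_lof_sets:
            raise KeyError(f"tip {tree.labels[i]!r} missing from lof_sets")
    n = len(tree)
    qualifies = [False] * n
    shared: list[set[str]] = [set() for _ in range(n)]
    order = sorted(range(n), key=lambda i: -len(tree.ancestors(i)))  # postorder
    for i in order:
        if tree.is_tip[i]:
            s = set(per_tip_lof_sets[tree.labels[i]])
            shared[i] = s
            qualifies[i] = bool(s)
        else:
            kids = tree.children[i]
            if all(qualifies[c] for c in kids):
                inter = set.intersection(*(shared[c] for c in kids))
                shared[i] = inter
                qualifies[i] = bool(inter)
    # maximal qualifying non-root nodes; when the root itself qualifies the
    # loss predates the tree and is placed on the root's child branches
    losses = [
        i for i in range(1, n)
        if qualifies[i] and (tree.parent[i] == 0 or not qualifies[tree.parent[i]])
    ]
    labels = [tree.labels[i] for i in losses]
    support = {tree.labels[i]: set(shared[i]) for i in losses}
    counts: dict[str, int] = {}
    for i in losses:
        cat = tree.category[i]
        if cat is not None:
            counts[cat] = counts.get(cat, 0) + 1
    return LossInference(labels, support, counts)


def count_losses_by_category(
    tree: Phylo, loss_branches: list[str]
) -> dict[str, dict[str, int]]:
    """Independent losses and intact branches per branch category.

    Independent losses in category c are the loss branches of category c
    with no loss branch among their ancestors; intact branches of category c
    are all category-c branches excluding loss branches and all their
    descendants.
    """
    loss_idx = {tree.index_of(lab) for lab in loss_branches}
    for i in tree.branches:
        if tree.category[i] is None:
            raise ValueError(
                f"branch above {tree.labels[i]!r} has no category"
            )
    independent = {
        i for i in loss_idx
        if not any(a in loss_idx for a in tree.ancestors(i))
    }
    excluded: set[int] = set()
    for i in independent:
        excluded.add(i)
        excluded.update(int(d) for d in tree.descendants(i))
    out: dict[str, dict[str, int]] = {}
    for i in tree.branches:
        cat = tree.category[i]
        entry = out.setdefault(cat, {"independent_losses": 0, "intact_branches": 0})
        if i in independent:
            entry["independent_losses"] += 1
        elif i not in excluded:
            entry["intact_branches"] += 1
    return out


# --- contingency tests -------------------------------------------------------


def _fisher_exact_2xk(table: np.ndarray, max_enumeration: int = 10 ** 6,
                      seed: int = 0, n_mc: int = 100000) -> float:
    """Two-sided Fisher exact test for a 2 x k table.

    Full enumeration of the fiber with fixed margins when the outcome space
    is small enough, else Monte-Carlo with a fixed seed. The p-value sums
    the probabilities of all tables at most as probable as the observed one.
    """
    col_sums = table.sum(axis=0)
    r0 = int(table[0].sum())
    n = int(table.sum())
    k = len(col_sums)

    def log_prob(xs) -> float:
        lp = -(math.lgamma(n + 1) - math.lgamma(r0 + 1) - math.lgamma(n - r0 + 1))
        for x, c in zip(xs, col_sums):
            lp += math.lgamma(c + 1) - math.lgamma(x + 1) - math.lgamma(c - x + 1)
        return lp

    obs_lp = log_prob(table[0])
    space = 1
    for c in col_sums:
        space *= int(c) + 1
    tol = 1e-9
    if space <= max_enumeration:
        total = 0.0
        p = 0.0
        for xs in itertools.product(*(range(int(c) + 1) for c in col_sums[:-1])):
            last = r0 - sum(xs)
            if last < 0 or last > col_sums[-1]:
                continue
            lp = log_prob(list(xs) + [last])
            prob = math.exp(lp)
            total += prob
            if lp <= obs_lp + tol:
                p += prob
        return min(1.0, p / total)
    rng = np.random.default_rng(seed)
    remaining = col_sums.astype(int)
    count = 0
    for _ in range(n_mc):
        xs = []
        left = r0
        pool = n
        for c in col_sums[:-1]:
            x = rng.hypergeometric(int(c), pool - int(c), left) if left > 0 else 0
            xs.append(x)
            left -= x
            pool -= int(c)
        xs.append(left)
        if log_prob(xs) <= obs_lp + tol:
            count += 1
    return count / n_mc


def contingency_tests(counts: np.ndarray | list) -> dict[str, float]:
    """Pearson chi-squared (no continuity correction) and Fisher exact test
    for a 2 x k lost/intact table."""
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.shape[0] != 2 or table.shape[1] < 2:
        raise ValueError("expected a 2 x k table with k >= 2")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    # categories with no branches at all are uninformative; drop them
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2 or table.sum(axis=1).min() == 0:
        return {"chi2_stat": 0.0, "chi2_p": 1.0, "fisher_p": 1.0}
    chi2, chi2_p, _, _ = stats.chi2_contingency(table, correction=False)
    if table.shape[1] == 2:
        _, fisher_p = stats.fisher_exact(table.astype(int))
    else:
        fisher_p = _fisher_exact_2xk(table.astype(int))
    return {"chi2_stat": float(chi2), "chi2_p": float(chi2_p),
            "fisher_p": float(fisher_p)}


# --- branch-drawing loss simulation ------------------------------------------


@dataclass
class SimulationResult:
    n_sims: int
    n_discarded: int
    distributions: dict[str, np.ndarray]
    p_values: dict[str, float]
    seed: int
    n_draws: int
    weighted: bool

    def to_json_dict(self) -> dict:
        return {
            "n_sims": self.n_sims,
            "n_discarded": self.n_discarded,
            "n_draws": self.n_draws,
            "weighted": self.weighted,
            "seed": self.seed,
            "p_values": {k: float(v) for k, v in sorted(self.p_values.items())},
            "mean_independent": {
                k: float(np.mean(v)) for k, v in sorted(self.distributions.items())
            },
        }


def simulate_random_losses(
    tree: Phylo,
    n_draws: int,
    weighted: bool = False,
    n_sims: int = 10000,
    seed: int = 0,
    observed_counts: dict[str, int] | None = None,
) -> SimulationResult:
    """Sequential random gene-loss placement on a category-labelled tree.

    Per replicate all branches start with a complete gene; branches are
    drawn sequentially (uniformly, or with probability proportional to
    branch length) among branches still complete, and a drawn branch and all
    its descendants become lost. Replicates in which the tree runs out of
    complete branches before ``n_draws`` placements are discarded and do not
    enter the p-value denominator. Independent losses per replicate are the
    drawn branches with no drawn ancestor; p-values compare the per-category
    independent-loss counts with the observed ones (P(count >= observed)).
    """
    branches = tree.branches
    B = len(branches)
    if n_draws > B:
        raise ValueError(
            f"cannot place {n_draws} losses on {B} branches"
        )
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    cats = [tree.category[i] for i in branches]
    if any(c is None for c in cats):
        raise ValueError("every branch must carry a category")
    cat_names = sorted(set(cats))
    cat_code = np.array([cat_names.index(c) for c in cats])
    lengths = tree.length[branches].astype(float)
    if weighted and lengths.sum() <= 0:
        raise ValueError("weighted drawing requires positive branch lengths")
    pos_of = {int(b): k for k, b in enumerate(branches)}
    desc_pos = [
        np.array([pos_of[int(d)] for d in tree.descendants(int(b))], dtype=np.int64)
        for b in branches
    ]
    anc_pos = [
        np.array([pos_of[a] for a in tree.ancestors(int(b)) if a in pos_of],
                 dtype=np.int64)
        for b in branches
    ]
    rng = np.random.default_rng(seed)
    dists = np.zeros((n_sims, len(cat_names)), dtype=np.int64)
    n_discarded = 0
    done = 0
    while done < n_sims:
        complete = np.ones(B, dtype=bool)
        drawn: list[int] = []
        ok = True
        for _ in range(n_draws):
            avail = np.flatnonzero(complete)
            if len(avail) == 0:
                ok = False
                break
            if weighted:
                w = lengths[avail]
                pick = int(avail[rng.choice(len(avail), p=w / w.sum())])
            else:
                pick = int(avail[rng.integers(len(avail))])
            drawn.append(pick)
            complete[pick] = False
            complete[desc_pos[pick]] = False
        if not ok:
            n_discarded += 1
            continue
        drawn_set = set(drawn)
        for pick in drawn:
            if not any(int(a) in drawn_set for a in anc_pos[pick]):
                dists[done, cat_code[pick]] += 1
        done += 1
    distributions = {c: dists[:, k].copy() for k, c in enumerate(cat_names)}
    p_values: dict[str, float] = {}
    if observed_counts:
        for c, obs in observed_counts.items():
            if c in distributions:
                p_values[c] = float(np.mean(distributions[c] >= obs))
            else:
                p_values[c] = 1.0 if obs <= 0 else 0.0
    return SimulationResult(
        n_sims=n_sims,
        n_discarded=n_discarded,
        distributions=distributions,
        p_values=p_values,
        seed=seed,
        n_draws=n_draws,
        weighted=weighted,
    )


# --- shared-missing-gene simulation ------------------------------------------


def simulate_shared_missing(
    gene_lengths: np.ndarray | list,
    per_species_missing_counts: list[int],
    weighted: bool = False,
    n_sims: int = 10000,
    seed: int = 0,
    observed: int | None = None,
) -> dict:
    """Null distribution of the number of genes missing in every species.

    Per replicate each species draws its number of missing genes from the
    universal gene set without replacement — uniformly, or sequentially with
    probability proportional to gene length — and the shared-missing count
    is the size of the intersection of the species' draws.
    """
    lengths = np.asarray(gene_lengths, dtype=float)
    G = len(lengths)
    if any(n > G for n in per_species_missing_counts):
        raise ValueError("a species cannot miss more genes than exist")
    if weighted:
        if (lengths < 0).any():
            raise ValueError("gene lengths must be >= 0")
        for n in per_species_missing_counts:
            if (lengths > 0).sum() < n:
                raise ValueError("not enough positively weighted genes")
    rng = np.random.default_rng(seed)
    shared = np.zeros(n_sims, dtype=np.int64)
    for rep in range(n_sims):
        inter: np.ndarray | None = None
        for n in per_species_missing_counts:
            if weighted:
                # exponential-key trick == sequential draw/remove/renormalize
                with np.errstate(divide="ignore"):
                    keys = rng.exponential(size=G) / lengths
                picked = np.argpartition(keys, n - 1)[:n] if n > 0 else np.array([], dtype=int)
            else:
                keys = rng.random(G)
                picked = np.argpartition(keys, n - 1)[:n] if n > 0 else np.array([], dtype=int)
            mask = np.zeros(G, dtype=bool)
            mask[picked] = True
            inter = mask if inter is None else (inter & mask)
        shared[rep] = int(inter.sum()) if inter is not None else 0
    out = {
        "distribution": shared,
        "mean": float(shared.mean()),
        "seed": seed,
        "weighted": weighted,
    }
    if observed is not None:
        out["p_shared_ge_observed"] = float(np.mean(shared >= observed))
    return out
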