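"""Shared fixtures and simulation helpers."""

import random

import dendropy
import numpy as np
import pandas as pd
import pytest

from chemomine.lossstats import Phylo
from chemomine.synthdata import (
    _receptor_protein,
    _reverse_translate,
    default_plant_specs,
    generate_synthetic_genome,
)


def yule_tree(n_tips: int, seed: int) -> Phylo:
    """Ultrametric pure-birth tree via dendropy, deterministic under seed."""
    tree = dendropy.model.birthdeath.birth_death_tree(
        1.0, 0.0, num_extant_tips=n_tips, rng=random.Random(seed)
    )
    return Phylo._from_dendropy(tree)


def simulate_bm(tree: Phylo, rng: np.random.Generator, sigma: float = 1.0) -> dict:
    """Brownian-motion tip values along the tree."""
    vals = np.zeros(len(tree))
    for i in range(1, len(tree)):
        vals[i] = vals[tree.parent[i]] + rng.normal(0, sigma * np.sqrt(tree.length[i]))
    return {tree.labels[i]: vals[i] for i in tree.tip_indices}


def receptor_and_cds(seed: int = 0, aa_len: int = 310):
    """A synthetic receptor protein and one exact coding sequence for it."""
    rng = np.random.default_rng(seed)
    prot = _receptor_protein(rng, aa_len)
    cds = _reverse_translate(prot, rng)
    return prot, cds


@pytest.fixture(scope="session")
def benchmark_genome():
    """One standard synthetic genome with its truth table and references."""
    specs = default_plant_specs(0)
    genome, truth, refdb = generate_synthetic_genome(
        specs, background_kb=1000, seed=1
    )
    return genome, truth, refdb


def make_loss_free_traits(tmp_path, n_tips: int = 24, seed: int = 12):
    """Write a Newick tree and a matching BM trait table; return the paths."""
    tree = yule_tree(n_tips, seed)
    rng = np.random.default_rng(seed)
    x = simulate_bm(tree, rng)
    noise = simulate_bm(tree, rng, 0.5)
    y = {k: 1.2 * x[k] + noise[k] for k in x}
    tree_path = tmp_path / "tree.nwk"
    tree_path.write_text(tree.to_newick() + "\n")
    traits_path = tmp_path / "traits.tsv"
    df = pd.DataFrame({"x": pd.Series(x), "y": pd.Series(y)})
    df.rename_axis("species_id").reset_index().to_csv(
        traits_path, sep="\t", index=False
    )
    return tree_path, traits_path


def match_candidates_to_truth(candidates, truth: pd.DataFrame):
    """Pair each truth row with overlapping same-family candidates."""
    pairs = []
    for _, row in truth.iterrows():
        matches = [
            c for c in candidates
            if c.model.span.scaffold_id == row.scaffold
            and c.model.span.start < row.end
            and row.start < c.model.span.end
            and c.family == row.family
        ]
        pairs.append((row, matches))
    return pairs
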