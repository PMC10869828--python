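"""Ground-truth generators for benchmarking.

Synthetic genomes with planted chemoreceptor genes in every status category
and synthetic trees with category-labelled branches and planted loss events.

Reference proteins are synthetic receptor-like sequences — seven hydrophobic
stretches joined by polar loops, so the Kyte-Doolittle seven-TM screen
passes — reverse-translated with uniform synonymous codon choice. Each plant
derives from its family's base protein with a small number of substitutions,
then applies its status recipe: loss-of-function mutations for pseudogenes,
5'-fragments for truncated/edge plants, N insertions for ambiguous plants,
and codon-aligned GT..AG introns for multi-exon plants. Background sequence
is i.i.d. with configurable GC; no repeat landscape is modelled.
"""

from __future__ import annotations

import json
import random as _random
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from ._align import revcomp
from .lossstats import Phylo
from .miner import RefRecord, ReferenceDB
from .seqcore import Genome

__all__ = [
    "PlantSpec",
    "generate_synthetic_genome",
    "generate_loss_scenario",
    "default_plant_specs",
]

# codons per amino acid (standard code), used for uniform reverse translation
_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "N": ["AAT", "AAC"], "D": ["GAT", "GAC"], "C": ["TGT", "TGC"],
    "Q": ["CAA", "CAG"], "E": ["GAA", "GAG"],
    "G": ["GGT", "GGC", "GGA", "GGG"], "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "K": ["AAA", "AAG"], "M": ["ATG"], "F": ["TTT", "TTC"],
    "P": ["CCT", "CCC", "CCA", "CCG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"], "W": ["TGG"],
    "Y": ["TAT", "TAC"], "V": ["GTT", "GTC", "GTA", "GTG"],
}
_AA20 = "".join(sorted(_CODONS))
_TM_ALPHABET = "ILVF"  # strongly hydrophobic
_LOOP_ALPHABET = "STGNQDEKRP"  # polar / charged

# per-family protein length (aa, incl. leading Met, excl. stop)
_FAMILY_AA_LEN = {
    "OR": 310, "TAAR": 300, "T2R": 300, "V1R": 300, "V2R": 900, "T1R": 900,
}
_DEFAULT_INTRONS = {"V1R": 2, "V2R": 5, "T1R": 5}


@dataclass
class PlantSpec:
    """Recipe for one planted gene."""

    family: str
    exon_mode: str = "single"  # single | multi
    target_status: str = "complete"
    strand: str = "+"
    placement: str = "free"  # free | near_border | with_ambiguity
    lof: list[tuple[str, int]] = field(default_factory=list)
    intron_count: int = 0
    intron_lengths: list[int] | None = None
    gtag: bool = True
    fragment_nt: int | None = None  # 5'-fragment length for truncated/edge
    n_ambiguous: int = 3

    def __post_init__(self):
        if (self.target_status == "pseudogene") != bool(self.lof):
            raise ValueError("LoF recipe required iff target is pseudogene")
        if self.placement == "near_border" and self.target_status != "edge":
            raise ValueError("near_border placement requires target edge")
        if self.target_status == "edge":
            self.placement = "near_border"
        if self.target_status == "ambiguous":
            self.placement = "with_ambiguity"


def _receptor_protein(rng: np.random.Generator, aa_len: int,
                      n_tm: int = 7, tm_len: int = 23, loop_len: int = 12) -> str:
    """Receptor-like protein: n_tm hydrophobic stretches joined by loops."""
    core = n_tm * tm_len + (n_tm + 1) * loop_len + 1
    if aa_len < core:
        raise ValueError(f"aa_len {aa_len} too short for {n_tm} TM segments")
    extra = aa_len - core  # padded into the N-terminal loop (ectodomain)
    parts = ["M"]
    parts.append("".join(rng.choice(list(_LOOP_ALPHABET), size=loop_len + extra)))
    for _ in range(n_tm):
        parts.append("".join(rng.choice(list(_TM_ALPHABET), size=tm_len)))
        parts.append("".join(rng.choice(list(_LOOP_ALPHABET), size=loop_len)))
    prot = "".join(parts)
    assert len(prot) == aa_len
    return prot


def _mutate_protein(protein: str, rng: np.random.Generator, rate: float) -> str:
    chars = list(protein)
    n_mut = int(round(rate * (len(chars) - 1)))
    positions = rng.choice(np.arange(1, len(chars)), size=n_mut, replace=False)
    for p in positions:
        old = chars[p]
        choices = [a for a in _AA20 if a != old]
        chars[p] = choices[int(rng.integers(len(choices)))]
    return "".join(chars)


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    codons = []
    for aa in protein:
        opts = _CODONS[aa]
        codons.append(opts[int(rng.integers(len(opts)))])
    return "".join(codons)


def _background(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=n, p=p)
    return (
        np.frombuffer(b"ACGT", dtype=np.uint8)[codes].tobytes().decode("ascii")
    )


_STOPSET = {"TAA", "TAG", "TGA"}


def _scrub_frame_stops(seq: str, rng: np.random.Generator) -> str:
    """Remove in-frame stop codons from a background stretch (frame 0)."""
    codons = [seq[i : i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)]
    for i, c in enumerate(codons):
        while c in _STOPSET:
            c = "".join("ACGT"[int(rng.integers(4))] for _ in range(3))
        codons[i] = c
    return "".join(codons) + seq[len(seq) - len(seq) % 3 :]


def build_reference_db(
    families: list[str], seed: int, refs_per_family: int = 3,
    divergence: float = 0.05,
) -> tuple[ReferenceDB, dict[str, str]]:
    """Synthetic reference database: per-family queries, outgroups, decoys.

    Returns the database and the per-family base protein used for plants.
    """
    records: list[RefRecord] = []
    base: dict[str, str] = {}
    for fi, fam in enumerate(sorted(set(families))):
        rng = np.random.default_rng([seed % (2 ** 31), 1000 + fi])
        prot = _receptor_protein(rng, _FAMILY_AA_LEN[fam])
        base[fam] = prot
        records.append(RefRecord(f"{fam}_ref1", prot, fam, "family_query", "a"))
        for k in range(2, refs_per_family + 1):
            records.append(
                RefRecord(
                    f"{fam}_ref{k}",
                    _mutate_protein(prot, rng, divergence),
                    fam,
                    "family_query",
                    "b",
                )
            )
    decoy_rng = np.random.default_rng([seed % (2 ** 31), 9999])
    for k in range(1, 4):
        records.append(
            RefRecord(
                f"DECOY_{k}",
                _receptor_protein(decoy_rng, 320),
                "OR" if "OR" in base else sorted(base)[0],
                "nonchemo_gpcr",
            )
        )
    records.append(
        RefRecord(
            "OUTGROUP_1",
            _receptor_protein(decoy_rng, 330),
            sorted(base)[0],
            "outgroup",
        )
    )
    return ReferenceDB(records), base


def _build_plant(
    spec: PlantSpec, base_protein: str, rng: np.random.Generator
) -> tuple[str, list[str], int]:
    """Construct the genomic insert for one plant.

    Returns (insert on the gene's own strand, LoF keys, cds_len). The insert
    is the CDS (with stop codon) for single-exon plants, or the CDS with
    codon-aligned introns for multi-exon plants; fragments are 5' pieces.
    """
    protein = _mutate_protein(base_protein, rng, 0.02)
    cds = _reverse_translate(protein, rng)
    stop = ["TAA", "TAG", "TGA"][int(rng.integers(3))]
    cds = cds + stop
    lof_keys: list[str] = []
    # status recipe on the spliced CDS
    if spec.target_status == "pseudogene":
        shift = 0
        parts = list(cds)
        for kind, codon in sorted(spec.lof, key=lambda x: x[1]):
            pos = 3 * (codon - 1) + shift
            if kind == "premature_stop":
                parts[pos : pos + 3] = list("TAA")
            elif kind == "frameshift_deletion":
                del parts[pos]
                shift -= 1
            elif kind == "frameshift_insertion":
                parts.insert(pos, "ACGT"[int(rng.integers(4))])
                shift += 1
            else:
                raise ValueError(f"unknown LoF kind {kind!r}")
            lof_keys.append(f"{kind}@{codon}")
        cds = "".join(parts)
    elif spec.target_status in ("truncated", "edge"):
        frag = spec.fragment_nt or (450 if len(cds) < 1500 else 900)
        frag -= frag % 3
        cds = cds[:frag]
    elif spec.target_status == "ambiguous":
        positions = rng.choice(
            np.arange(30, len(cds) - 33), size=spec.n_ambiguous, replace=False
        )
        parts = list(cds)
        for p in positions:
            parts[int(p)] = "N"
        cds = "".join(parts)
    cds_len = len(cds)

    if spec.exon_mode == "single" or spec.intron_count == 0:
        return cds, lof_keys, cds_len

    # insert codon-aligned GT..AG introns
    n_introns = spec.intron_count
    lengths = spec.intron_lengths or [
        int(rng.integers(150, 400)) for _ in range(n_introns)
    ]
    n_codons = len(cds) // 3
    if n_codons < (n_introns + 1) * 25:
        n_introns = max(0, n_codons // 25 - 1)
        lengths = lengths[:n_introns]
    cut_codons = sorted(
        rng.choice(np.arange(20, n_codons - 20), size=n_introns, replace=False)
    )
    # enforce a minimum exon size between cuts
    ok_cuts = []
    last = 0
    for c in cut_codons:
        if c - last >= 20:
            ok_cuts.append(int(c))
            last = int(c)
    pieces = []
    prev = 0
    for ci, cut in enumerate(ok_cuts):
        pieces.append(cds[3 * prev : 3 * cut])
        ilen = lengths[ci % len(lengths)]
        inner = _background(rng, ilen - 4, 0.4)
        intron = ("GT" + inner + "AG") if spec.gtag else ("CT" + inner + "TG")
        pieces.append(intron)
        prev = cut
    pieces.append(cds[3 * prev :])
    return "".join(pieces), lof_keys, cds_len


def default_plant_specs(seed: int = 0) -> list[PlantSpec]:
    """A representative benchmark plan spanning all five statuses and both
    exon modes (14 plants: OR and TAAR single-exon, V2R multi-exon)."""
    return [
        PlantSpec("OR", "single", "complete", "+"),
        PlantSpec("OR", "single", "complete", "-"),
        PlantSpec("OR", "single", "complete", "+"),
        PlantSpec("OR", "single", "pseudogene", "+",
                  lof=[("premature_stop", 120)]),
        PlantSpec("OR", "single", "pseudogene", "-",
                  lof=[("frameshift_deletion", 140)]),
        PlantSpec("OR", "single", "truncated", "+"),
        PlantSpec("OR", "single", "edge", "+"),
        PlantSpec("OR", "single", "ambiguous", "+"),
        PlantSpec("TAAR", "single", "complete", "+"),
        PlantSpec("TAAR", "single", "pseudogene", "+",
                  lof=[("premature_stop", 90), ("premature_stop", 180)]),
        PlantSpec("V2R", "multi", "complete", "+", intron_count=5),
        PlantSpec("V2R", "multi", "complete", "-", intron_count=3),
        PlantSpec("V2R", "multi", "pseudogene", "+", intron_count=4,
                  lof=[("premature_stop", 400)]),
        PlantSpec("V2R", "multi", "truncated", "+", intron_count=1,
                  fragment_nt=900),
    ]


def generate_synthetic_genome(
    specs: list[PlantSpec],
    background_kb: int = 1000,
    gc: float = 0.42,
    seed: int = 0,
) -> tuple[Genome, pd.DataFrame, ReferenceDB]:
    """Build a genome with planted genes, its truth table and a reference DB.

    Single-exon plants live on ``sc_single``, multi-exon plants on
    ``sc_multi`` (padded so 30 kb flank extensions never hit a scaffold
    end), and each edge plant gets its own small scaffold with the
    truncated gene end close to the border. Fully deterministic under
    ``seed``.
    """
    if not specs:
        raise ValueError("at least one plant spec is required")
    rng = np.random.default_rng(seed % (2 ** 31))
    families = sorted({s.family for s in specs})
    refdb, base = build_reference_db(families, seed)

    singles = [s for s in specs if s.exon_mode == "single" and s.target_status != "edge"]
    multis = [s for s in specs if s.exon_mode == "multi" and s.target_status != "edge"]
    edges = [s for s in specs if s.target_status == "edge"]

    truth_rows: list[dict] = []
    scaffolds: dict[str, str] = {}
    budget = background_kb * 1000

    def place_scaffold(name: str, plants: list[PlantSpec], pad: int, gap: int):
        nonlocal budget
        parts: list[str] = []
        pos = 0
        pad_seq = _background(rng, pad, gc)
        parts.append(pad_seq)
        pos += pad
        budget_used = pad
        for spec in plants:
            insert, lof_keys, cds_len = _build_plant(spec, base[spec.family], rng)
            oriented = insert if spec.strand == "+" else revcomp(insert)
            start, end = pos, pos + len(oriented)
            parts.append(oriented)
            pos = end
            truth_rows.append(
                dict(
                    scaffold=name, start=start, end=end, strand=spec.strand,
                    family=spec.family, target_status=spec.target_status,
                    lof_keys=";".join(lof_keys), cds_len=cds_len,
                )
            )
            g = gap + int(rng.integers(0, gap // 2 + 1))
            gseq = _background(rng, g, gc)
            if spec.target_status in ("truncated", "edge") and spec.strand == "+":
                # a stray in-frame continuation must not complete the ORF;
                # background provides stops naturally, nothing to scrub
                pass
            parts.append(gseq)
            pos += g
            budget_used += len(oriented) - cds_len + g  # introns count as background
        parts.append(pad_seq[::-1])
        pos += pad
        budget_used += pad
        budget -= budget_used
        scaffolds[name] = "".join(parts)

    if singles:
        place_scaffold("sc_single", singles, pad=2000, gap=3000)
    if multis:
        place_scaffold("sc_multi", multis, pad=32000, gap=3000)
    for i, spec in enumerate(edges):
        margin = 120 if spec.exon_mode == "single" else 1000
        insert, lof_keys, cds_len = _build_plant(spec, base[spec.family], rng)
        lead = _background(rng, 3000, gc)
        tail = _background(rng, margin, gc)
        name = f"sc_edge{i}"
        if spec.strand == "+":
            seq = lead + insert + tail
            start, end = len(lead), len(lead) + len(insert)
        else:
            seq = tail + revcomp(insert) + lead
            start, end = margin, margin + len(insert)
        scaffolds[name] = seq
        budget -= len(seq) - cds_len
        truth_rows.append(
            dict(
                scaffold=name, start=start, end=end, strand=spec.strand,
                family=spec.family, target_status="edge",
                lof_keys=";".join(lof_keys), cds_len=cds_len,
            )
        )
    if budget < 0:
        raise ValueError(
            f"background_kb={background_kb} too small to host all plants "
            f"(short by {-budget} bp)"
        )
    if budget > 0:
        scaffolds["sc_background"] = _background(rng, budget, gc)
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "scaffold", "start", "end", "strand", "family",
            "target_status", "lof_keys", "cds_len",
        ],
    )
    return Genome(scaffolds), truth, refdb


def write_synthetic_dataset(
    outdir: str | Path,
    genome: Genome,
    truth: pd.DataFrame,
    refdb: ReferenceDB,
    params: dict,
) -> None:
    """Write genome/reference FASTA, truth TSV + GFF3, provenance JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome.to_fasta(outdir / "genome.fasta")
    refdb.to_fasta(outdir / "references.fasta")
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    with open(outdir / "truth.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for i, row in truth.iterrows():
            fh.write(
                f"{row.scaffold}\tsynthdata\tgene\t{row.start + 1}\t{row.end}\t.\t"
                f"{row.strand}\t.\tID=plant{i};family={row.family};"
                f"status={row.target_status};lof={row.lof_keys or 'none'}\n"
            )
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(params, fh, indent=2, sort_keys=True)


# --- loss scenarios ----------------------------------------------------------


def generate_loss_scenario(
    n_tips: int,
    birth_rate: float = 1.0,
    category_switch_prob: float = 0.15,
    n_losses: int = 2,
    seed: int = 0,
    categories: tuple[str, ...] = ("carnivore", "herbivore", "omnivore"),
) -> tuple[Phylo, list[str], dict[str, set[str]], dict[str, str]]:
    """Yule tree with categorized branches and planted loss events.

    Categories follow a root-to-tip Markov relabeling (switch probability
    per branch). Loss branches are drawn sequentially among branches still
    carrying a complete gene, exactly as in the loss simulation, except that
    a draw that is an ancestor of an earlier draw is redrawn so exactly
    ``n_losses`` independent (maximal) lost clades exist. Every tip below a
    loss branch receives that branch's shared LoF key plus 0-2 private LoF
    mutations. Deterministic under ``seed``.

    Returns (tree, true loss-branch labels, per-tip LoF sets, per-branch
    categories keyed by node label).
    """
    pyrand = _random.Random(seed % (2 ** 31))
    tree = dendropy.model.birthdeath.birth_death_tree(
        birth_rate, 0.0, num_extant_tips=n_tips, rng=pyrand,
    )
    phylo = Phylo._from_dendropy(tree)
    n = len(phylo)
    if n_losses >= n - 1:
        raise ValueError(
            f"cannot plant {n_losses} losses on {n - 1} non-root branches"
        )
    rng = np.random.default_rng([seed % (2 ** 31), 77])
    # root-to-tip Markov category relabeling
    cats = [None] * n
    cats[0] = categories[int(rng.integers(len(categories)))]
    for i in range(1, n):
        parent_cat = cats[phylo.parent[i]]
        if rng.random() < category_switch_prob:
            others = [c for c in categories if c != parent_cat]
            cats[i] = others[int(rng.integers(len(others)))]
        else:
            cats[i] = parent_cat
    for i in range(n):
        phylo.category[i] = cats[i]

    branches = phylo.branches
    pos_of = {int(b): k for k, b in enumerate(branches)}
    drawn: list[int] = []
    for _restart in range(1000):
        complete = np.ones(len(branches), dtype=bool)
        drawn = []
        attempts = 0
        failed = False
        while len(drawn) < n_losses:
            avail = np.flatnonzero(complete)
            if len(avail) == 0 or attempts > 200:
                failed = True  # scenario exhausted the tree: restart
                break
            pick_pos = int(avail[rng.integers(len(avail))])
            node = int(branches[pick_pos])
            # a pick inside a lost clade is impossible (those branches are
            # no longer complete); redraw a pick that is an ancestor of an
            # earlier draw so the planted losses are exactly n_losses
            # maximal clades
            drawn_nodes = {int(branches[p]) for p in drawn}
            if any(node in phylo.ancestors(dn) for dn in drawn_nodes):
                attempts += 1
                continue
            drawn.append(pick_pos)
            complete[pick_pos] = False
            for d in phylo.descendants(node):
                if int(d) in pos_of:
                    complete[pos_of[int(d)]] = False
        if not failed:
            break
    else:
        raise ValueError("could not place independent losses on this tree")
    loss_nodes = [int(branches[p]) for p in drawn]
    loss_labels = [phylo.labels[i] for i in loss_nodes]

    lof_sets: dict[str, set[str]] = {
        phylo.labels[i]: set() for i in phylo.tip_indices
    }
    private_pos = 500
    for k, node in enumerate(loss_nodes):
        shared = f"premature_stop@{100 + 10 * k}"
        tips = phylo.tips_below(node)
        for t in tips:
            lab = phylo.labels[t]
            lof_sets[lab].add(shared)
            for _ in range(int(rng.integers(0, 3))):
                lof_sets[lab].add(f"frameshift_deletion@{private_pos}")
                private_pos += 1
    cat_map = {phylo.labels[i]: cats[i] for i in range(1, n)}
    return phylo, loss_labels, lof_sets, cat_map
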