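"""Chemoreceptor gene mining.

Two mining procedures are implemented, mirroring the biology of the six
GPCR chemoreceptor families:

* single-exon (OR, TAAR, most V1R, T2R): translated homology search at
  e <= 1e-5, best-hit region extraction, 1 kb flank extension, ORF scan at
  the family's minimum complete length, family assignment against a mixed
  reference/decoy database; then a second, more stringent search round
  (e <= 1e-20) seeded with the completes themselves to recover pseudogenes,
  truncated fragments and assembly-edge fragments.

* multi-exon (V2R, T1R, ray-finned-fish V1R): translated search, 30 kb
  per-hit extension and union, exon-count inference from hit spacing
  (>= 50 bp hits, >= 100 bp gaps), spliced gene-model prediction by
  seed chaining with a GT..AG intron bonus, then the iterative
  length-threshold / exon-cap / best-score selection loop.

Every retained candidate gets exactly one of five statuses: complete,
pseudogene, truncated, edge or ambiguous.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import seqcore
from ._align import (
    encode_dna,
    encode_protein,
    evalue as _ka_evalue,
    NT_KA_K,
    NT_KA_LAMBDA,
    nt_seed_segments,
    protein_identity,
    protein_score,
    revcomp,
    seed_segments,
    translate_codes,
    decode_protein,
)
from ._lofdp import LofAlignment, align_dna_to_protein
from .seqcore import (
    ExtendedRegion,
    Genome,
    GenomicInterval,
    TranslatedHit,
)

FAMILIES = ("OR", "TAAR", "V1R", "V2R", "T1R", "T2R")
STATUSES = ("complete", "pseudogene", "truncated", "edge", "ambiguous")
ROLES = ("family_query", "outgroup", "nonchemo_gpcr")

STOP_CODONS = {"TAA", "TAG", "TGA"}


# --- reference database ------------------------------------------------------


@dataclass(frozen=True)
class RefRecord:
    ref_id: str
    protein: str
    family: str
    role: str = "family_query"
    subclade: str | None = None

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")


class ReferenceDB:
    """GPCR protein references: per-family queries, outgroups and decoys."""

    def __init__(self, records: list[RefRecord]):
        ids = [r.ref_id for r in records]
        dupes = {i for i, c in Counter(ids).items() if c > 1}
        if dupes:
            raise ValueError(f"duplicate reference ids: {sorted(dupes)}")
        self.records = list(records)
        self._by_id = {r.ref_id: r for r in records}

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, ref_id: str) -> RefRecord:
        return self._by_id[ref_id]

    def queries(self, family: str) -> list[RefRecord]:
        return [
            r for r in self.records
            if r.family == family and r.role == "family_query"
        ]

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceDB":
        """Parse a FASTA whose headers carry ``family=.. role=.. subclade=..``."""
        records = []
        with open(path) as fh:
            for rec in SeqIO.parse(fh, "fasta"):
                tokens = dict(
                    t.split("=", 1) for t in rec.description.split()[1:] if "=" in t
                )
                records.append(
                    RefRecord(
                        rec.id,
                        str(rec.seq).upper(),
                        tokens.get("family", "OR"),
                        tokens.get("role", "family_query"),
                        tokens.get("subclade"),
                    )
                )
        return cls(records)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.records:
                extra = f" subclade={r.subclade}" if r.subclade else ""
                fh.write(f">{r.ref_id} family={r.family} role={r.role}{extra}\n")
                fh.write(r.protein + "\n")


# --- per-family parameters ---------------------------------------------------


@dataclass
class FamilyParams:
    """Mining thresholds for one family.

    Defaults follow the standard per-family length and stringency tiers.
    """

    family: str
    exon_mode: str  # "single" | "multi"
    min_complete_nt: int
    flank_bp: int
    search_evalue: float = 1e-5
    rescan_evalue: float = 1e-20
    mean_expected_nt: int | None = None
    min_report_nt: int = 0
    exon_hit_min_bp: int = 50
    exon_gap_min_bp: int = 100
    require_start: bool = True
    stop_margin: int = 15
    tm_min: int = 6
    classify_min_score: float = 80.0
    min_fragment_score: int = 60

    def __post_init__(self):
        if self.exon_mode not in ("single", "multi"):
            raise ValueError("exon_mode must be 'single' or 'multi'")
        if self.min_report_nt > self.min_complete_nt:
            raise ValueError("min_report_nt must be <= min_complete_nt")


_SINGLE_MIN = {"OR": 750, "T2R": 750, "V1R": 810, "TAAR": 850}
_MULTI = {
    # family: (min_complete_nt, mean_expected_nt, min_report_nt)
    "V1R": (810, 900, 0),
    "V2R": (2100, 2700, 400),
    "T1R": (2200, 2700, 400),
}


def default_family_params(family: str, exon_mode: str | None = None) -> FamilyParams:
    """Default parameters (standard length/stringency tiers) for one family.

    V1R supports both modes (single-exon outside ray-finned fishes,
    multi-exon within); the other families have a fixed mode.
    """
    if exon_mode is None:
        exon_mode = "multi" if family in ("V2R", "T1R") else "single"
    if exon_mode == "single":
        if family not in _SINGLE_MIN:
            raise ValueError(f"{family} has no single-exon procedure")
        return FamilyParams(family, "single", _SINGLE_MIN[family], flank_bp=1000)
    if family not in _MULTI:
        raise ValueError(f"{family} has no multi-exon procedure")
    mc, me, mr = _MULTI[family]
    return FamilyParams(
        family, "multi", mc, flank_bp=30000, mean_expected_nt=me, min_report_nt=mr
    )


# --- gene models and candidates ----------------------------------------------


@dataclass
class GeneModel:
    """Exon structure of one mined locus (exons in transcription order)."""

    exons: list[GenomicInterval]
    cds_nt: str
    score: float
    ref_id: str | None = None

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def scaffold_id(self) -> str:
        return self.exons[0].scaffold_id

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.scaffold_id,
            min(e.start for e in self.exons),
            max(e.end for e in self.exons),
            self.strand,
        )


@dataclass(frozen=True)
class LoFEvent:
    kind: str  # premature_stop | frameshift_insertion | frameshift_deletion
    ref_codon_position: int  # 1-based codon index on the matched reference

    def __post_init__(self):
        if self.ref_codon_position < 1:
            raise ValueError("ref_codon_position must be >= 1")

    @property
    def key(self) -> str:
        return f"{self.kind}@{self.ref_codon_position}"


@dataclass
class GeneCandidate:
    family: str
    model: GeneModel
    status: str
    lof: list[LoFEvent] = field(default_factory=list)
    tm_count: int | None = None
    tm_pass: bool | None = None
    best_ref_id: str | None = None
    best_ref_identity: float | None = None
    clipped_start: bool = False
    clipped_end: bool = False
    protein: str = ""


class Repertoire:
    """Per-species, per-family counts of candidates by status."""

    def __init__(self):
        self.counts: dict[str, dict[str, Counter]] = {}

    def add(self, species_id: str, family: str, status: str, n: int = 1) -> None:
        fam = self.counts.setdefault(species_id, {}).setdefault(family, Counter())
        fam[status] += n

    def add_candidates(self, species_id: str, candidates: list[GeneCandidate]) -> None:
        for c in candidates:
            self.add(species_id, c.family, c.status)

    def total(self, species_id: str, family: str) -> int:
        return sum(self.counts.get(species_id, {}).get(family, Counter()).values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sp, fams in sorted(self.counts.items()):
            for fam, ctr in sorted(fams.items()):
                row = {"species_id": sp, "family": fam}
                row.update({s: ctr.get(s, 0) for s in STATUSES})
                row["total"] = sum(ctr.values())
                rows.append(row)
        return pd.DataFrame(rows, columns=["species_id", "family", *STATUSES, "total"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# --- exon-count inference ----------------------------------------------------


def infer_exon_count(
    spans: list[tuple[int, int]],
    exon_hit_min_bp: int = 50,
    exon_gap_min_bp: int = 100,
) -> int:
    """Putative exon count from translated-search hit spans on one strand.

    Hits shorter than ``exon_hit_min_bp`` are dropped; remaining hits whose
    gap is smaller than ``exon_gap_min_bp`` are merged into one block; the
    number of merged blocks is returned.
    """
    kept = sorted(
        (s, e) for s, e in spans if e - s >= exon_hit_min_bp
    )
    if not kept:
        return 0
    blocks = 1
    cur_end = kept[0][1]
    for s, e in kept[1:]:
        if s - cur_end >= exon_gap_min_bp:
            blocks += 1
        cur_end = max(cur_end, e)
    return blocks


# --- spliced gene-model prediction (seed chaining) ---------------------------

_MIN_INTRON_NT = 40
_MAX_INTRON_NT = 10000
_INTRON_PENALTY = 25
_INTRON_NT_COST = 1 / 200  # long introns cost extra, per nt
_GTAG_BONUS = 15
_MIN_SEED_SCORE = 45
_MIN_CHAIN_SCORE = 60
_MAX_QUERY_OVERLAP = 30


def predict_gene_models(
    genome: Genome,
    region: GenomicInterval,
    ref_protein: str,
    params: FamilyParams,
    ref_id: str | None = None,
) -> list[GeneModel]:
    """Predict spliced gene models for one reference protein in a region.

    Exon seeds are ungapped protein-to-translated-DNA alignments above a
    score floor; collinear, non-overlapping seeds on one strand are chained
    by dynamic programming, maximizing total seed score minus an intron
    penalty per junction, with a bonus when the intron is GT..AG. Each
    maximal chain is emitted as a GeneModel.
    """
    seq = genome.slice(region)
    ref_codes = encode_protein(ref_protein.replace("*", ""))
    models: list[GeneModel] = []
    for strand in ("+", "-"):
        oriented = seq if strand == "+" else revcomp(seq)
        codes = encode_dna(oriented)
        seeds = []
        for frame in range(3):
            target = translate_codes(codes, frame)
            for seg in seed_segments(
                ref_codes, target, min_score=_MIN_SEED_SCORE
            ):
                seeds.append(
                    dict(
                        qs=seg.q_start,
                        qe=seg.q_end,
                        ts=frame + 3 * seg.t_start,
                        te=frame + 3 * seg.t_end,
                        score=seg.score,
                    )
                )
        models.extend(
            _chain_seeds_to_models(seeds, oriented, strand, region, ref_id)
        )
    models.sort(key=lambda m: (m.span.start, m.span.end, m.strand))
    return models


def _chain_seeds_to_models(seeds, oriented, strand, region, ref_id):
    models = []
    seeds = sorted(seeds, key=lambda s: (s["ts"], s["qs"]))
    used = [False] * len(seeds)
    while True:
        order = [i for i in range(len(seeds)) if not used[i]]
        if not order:
            break
        best = {i: seeds[i]["score"] for i in order}
        back: dict[int, int | None] = {i: None for i in order}
        for ii, i in enumerate(order):
            si = seeds[i]
            for j in order[:ii]:
                sj = seeds[j]
                q_overlap = sj["qe"] - si["qs"]
                if q_overlap > _MAX_QUERY_OVERLAP or sj["qs"] >= si["qs"]:
                    continue
                gap = si["ts"] - (sj["te"] - 3 * max(0, q_overlap))
                if gap < -4:  # small slop tolerates frameshifted junctions
                    continue
                if gap > _MAX_INTRON_NT:
                    continue
                if gap >= _MIN_INTRON_NT:
                    penalty = _INTRON_PENALTY + gap * _INTRON_NT_COST
                    d_end = sj["te"] - 3 * max(0, q_overlap)
                    if (
                        oriented[d_end : d_end + 2] == "GT"
                        and oriented[si["ts"] - 2 : si["ts"]] == "AG"
                    ):
                        penalty -= _GTAG_BONUS
                else:
                    penalty = _INTRON_PENALTY  # sub-intron gap: discouraged
                cand = best[j] + si["score"] - penalty
                if cand > best[i]:
                    best[i] = cand
                    back[i] = j
        top = max(order, key=lambda i: (best[i], -seeds[i]["ts"]))
        if best[top] < _MIN_CHAIN_SCORE:
            break
        chain = []
        node: int | None = top
        while node is not None:
            chain.append(node)
            used[node] = True
            node = back[node]
        chain.reverse()
        model = _emit_model(
            [seeds[i] for i in chain], oriented, strand, region, best[top], ref_id
        )
        if model is not None:
            models.append(model)
    return models


def _refine_junction(prev, nxt, oriented):
    """Pick the exon boundary at a junction by locating the GT..AG intron.

    Seed extension can overshoot an exon end (or undershoot the next exon's
    start) by a few residues when the intron translation matches by chance.
    Candidate split points in query coordinates near the seed-derived
    boundary are tested for a GT donor / AG acceptor pair; the first match
    (closest to the midpoint of the two seed-derived boundaries) wins, else
    the plain overlap-trim rule applies.
    """
    qe_j, te_j = prev["qe"], prev["te"]
    qs_k, ts_k = nxt["qs"], nxt["ts"]
    if qs_k - qe_j > 2:
        # a real query gap: the residues are missing, do not stretch exons
        # over intron sequence to cover them
        return None
    mid = (qe_j + qs_k) / 2.0
    lo = max(prev["qs"] + 1, min(qe_j, qs_k) - 2)
    hi = min(nxt["qe"] - 1, max(qe_j, qs_k) + 2)
    candidates = sorted(range(lo, hi + 1), key=lambda q: (abs(q - mid), q))
    for q in candidates:
        d_end = te_j - 3 * (qe_j - q)
        a_start = ts_k + 3 * (q - qs_k)
        if d_end <= prev["ts"] or a_start >= nxt["te"] or a_start - d_end < 4:
            continue
        if (
            oriented[d_end : d_end + 2] == "GT"
            and oriented[a_start - 2 : a_start] == "AG"
        ):
            return q
    return None


def _emit_model(chain, oriented, strand, region, score, ref_id):
    # resolve junctions: GT..AG refinement first, then plain overlap trimming
    # of the earlier exon's end
    exon_spans = []
    for k, s in enumerate(chain):
        qs, qe, ts, te = s["qs"], s["qe"], s["ts"], s["te"]
        if k + 1 < len(chain):
            nxt = chain[k + 1]
            q_split = _refine_junction(s, nxt, oriented)
            if q_split is not None:
                shift_next = q_split - nxt["qs"]
                nxt["qs"] = q_split
                nxt["ts"] = nxt["ts"] + 3 * shift_next
                qe = q_split
                te = s["te"] - 3 * (s["qe"] - q_split)
            else:
                overlap = qe - nxt["qs"]
                if overlap > 0:
                    qe -= overlap
                    te -= 3 * overlap
                if te > nxt["ts"]:  # residual target overlap from slop
                    te = nxt["ts"]
        if te > ts:
            exon_spans.append((ts, te))
    if not exon_spans:
        return None
    # recover a short unmatched head: seed extension can stop a residue or
    # two after the start codon when the plant diverges there
    first_qs = chain[0]["qs"]
    first_s, first_e = exon_spans[0]
    if 0 < first_qs <= 5:
        back = first_s - 3 * first_qs
        if back >= 0 and oriented[back : back + 3] == "ATG":
            exon_spans[0] = (back, first_e)
    # include the terminal stop codon; look ahead a few codons in case the
    # extension stopped just short of the reference C-terminus
    last_s, last_e = exon_spans[-1]
    for k in range(6):
        codon = oriented[last_e + 3 * k : last_e + 3 * k + 3]
        if len(codon) < 3:
            break
        if codon in STOP_CODONS:
            exon_spans[-1] = (last_s, last_e + 3 * k + 3)
            break
    cds = "".join(oriented[s:e] for s, e in exon_spans)
    n = len(oriented)
    exons = []
    for s, e in exon_spans:
        if strand == "+":
            iv = GenomicInterval(
                region.scaffold_id, region.start + s, region.start + e, "+"
            )
        else:
            iv = GenomicInterval(
                region.scaffold_id, region.start + (n - e), region.start + (n - s), "-"
            )
        exons.append(iv)
    return GeneModel(exons=exons, cds_nt=cds, score=float(score), ref_id=ref_id)


def read_gene_models_gff3(
    path: str | Path, genome: Genome
) -> list[GeneModel]:
    """Import externally produced spliced predictions (GFF3 gene/exon rows).

    Rows are grouped by the Parent/ID attribute of exon features; the score
    column of the gene row (or the sum of exon scores) is used as the model
    score. This is the fidelity escape hatch for users running a dedicated
    spliced aligner.
    """
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ValueError(f"malformed GFF3 row: {line!r}")
            sid, _, ftype, start, end, score, strand, _, attrs = parts
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "gene":
                gid = attr.get("ID", f"gene{len(genes)}")
                genes.setdefault(gid, {"exons": [], "score": 0.0})
                if score not in (".", ""):
                    genes[gid]["score"] = float(score)
            elif ftype in ("exon", "CDS"):
                gid = attr.get("Parent", attr.get("ID", "gene0"))
                genes.setdefault(gid, {"exons": [], "score": 0.0})
                genes[gid]["exons"].append(
                    GenomicInterval(sid, int(start) - 1, int(end), strand)
                )
    models = []
    for gid, g in genes.items():
        if not g["exons"]:
            continue
        strand = g["exons"][0].strand
        exons = sorted(g["exons"], key=lambda e: e.start, reverse=(strand == "-"))
        cds = "".join(genome.fetch(e) for e in exons)
        models.append(GeneModel(exons=exons, cds_nt=cds, score=g["score"], ref_id=gid))
    return models


# --- iterative model selection -----------------------------------------------


def select_gene_models(
    predictions: list[GeneModel],
    exon_cap: int,
    params: FamilyParams,
) -> list[GeneModel]:
    """Iterative acceptance of gene models under the exon-cap/length/score filters.

    Predictions with more exons than ``exon_cap`` are discarded. A length
    threshold L starts at the family's mean expected CDS length; models with
    CDS >= L are kept, among overlapping survivors the best-scoring one is
    accepted, accepted models and anything overlapping them are removed,
    then L is halved (never below the reporting floor) and the loop repeats
    until an iteration at the floor accepts nothing.
    """
    floor = max(params.min_report_nt, 30)
    pool = [p for p in predictions if p.exon_count <= exon_cap]
    pool.sort(key=lambda m: (-m.score, m.span.start, m.ref_id or ""))
    accepted: list[GeneModel] = []
    L = float(params.mean_expected_nt or params.min_complete_nt)
    while True:
        qualified = [
            p for p in pool
            if len(p.cds_nt) >= L
            and not any(p.span.overlaps(a.span) for a in accepted)
        ]
        newly = []
        for p in qualified:  # already sorted best-first
            if not any(p.span.overlaps(q.span) for q in newly):
                newly.append(p)
        accepted.extend(newly)
        if newly:
            pool = [
                p for p in pool
                if not any(p.span.overlaps(a.span) for a in accepted)
            ]
        if L <= floor and not newly:
            break
        L = max(L / 2.0, floor)
    accepted.sort(key=lambda m: (m.span.scaffold_id, m.span.start))
    return accepted


# --- family assignment -------------------------------------------------------


def classify_family(
    protein: str,
    refdb: ReferenceDB,
    min_score: float = 80.0,
) -> tuple[str | None, str | None, float]:
    """Best-match family assignment against the full reference database.

    The protein is scored against every record (exact local alignment,
    BLOSUM62); the family of the top record is returned, or None when the
    top record is an outgroup/decoy or the top score is below ``min_score``.
    Ties break by (score desc, ref_id lexicographic).
    """
    if not protein:
        raise ValueError("cannot classify an empty protein")
    best: tuple[float, str] | None = None
    for rec in refdb.records:
        s = protein_score(protein, rec.protein)
        if best is None or s > best[0] or (s == best[0] and rec.ref_id < best[1]):
            best = (s, rec.ref_id)
    assert best is not None
    score, ref_id = best
    rec = refdb[ref_id]
    if score < min_score or rec.role != "family_query":
        return None, ref_id, score
    return rec.family, ref_id, score


# --- LoF detection and status ------------------------------------------------


def detect_lof(
    candidate_nt: str,
    ref_protein: str,
    stop_margin: int = 15,
) -> list[LoFEvent]:
    """Loss-of-function events from a frameshift-aware candidate/reference
    alignment: premature stops at least ``stop_margin`` codons before the
    reference C-terminus, and indels whose net length is not a multiple of
    three, each located at its reference codon."""
    aln = detect_lof_alignment(candidate_nt, ref_protein, stop_margin)
    if aln.score < 20:
        raise ValueError("candidate does not align to the reference protein")
    return [LoFEvent(kind, pos) for kind, pos in aln.events]


def detect_lof_alignment(
    candidate_nt: str, ref_protein: str, stop_margin: int = 15
) -> LofAlignment:
    return align_dna_to_protein(candidate_nt, ref_protein, stop_margin)


def coding_identity(nt_a: str, nt_b: str) -> float:
    """Nucleotide identity over the protein-guided codon alignment.

    The two coding sequences are translated (up to the first stop), the
    proteins are aligned globally, and the alignment is threaded back onto
    codons; identity is the fraction of identical nucleotides over the
    aligned codon columns (gap columns excluded). Synonymous divergence
    therefore lowers the identity even when the proteins are identical.
    """
    from ._align import _clean_protein, _global_aligner

    aa_a = decode_protein(translate_codes(encode_dna(nt_a), 0)).split("*")[0]
    aa_b = decode_protein(translate_codes(encode_dna(nt_b), 0)).split("*")[0]
    aa_a, aa_b = _clean_protein(aa_a), _clean_protein(aa_b)
    if not aa_a or not aa_b:
        return 0.0
    aln = _global_aligner().align(aa_a, aa_b)[0]
    match = cols = 0
    for (a_block, b_block) in zip(*aln.aligned):
        a_start, a_end = a_block
        b_start, b_end = b_block
        for i in range(a_end - a_start):
            ca = nt_a[3 * (a_start + i) : 3 * (a_start + i) + 3]
            cb = nt_b[3 * (b_start + i) : 3 * (b_start + i) + 3]
            cols += 3
            match += sum(x == y for x, y in zip(ca, cb))
    return match / cols if cols else 0.0


_AMBIG_RE = re.compile(r"[^ACGT]")


def cds_is_intact(cds_nt: str) -> bool:
    """ATG start, terminal stop, in-frame, no internal stop, no ambiguity."""
    if len(cds_nt) < 6 or len(cds_nt) % 3 != 0:
        return False
    if _AMBIG_RE.search(cds_nt):
        return False
    if not cds_nt.startswith("ATG"):
        return False
    if cds_nt[-3:] not in STOP_CODONS:
        return False
    aa = decode_protein(translate_codes(encode_dna(cds_nt), 0))
    return "*" not in aa[:-1]


def assign_status(
    cds_nt: str,
    lof: list[LoFEvent],
    border_clipped: bool,
    params: FamilyParams,
) -> str:
    """Five-way status decision.

    Order: ambiguity code anywhere in the CDS -> ambiguous; intact CDS of at
    least the family minimum -> complete; any LoF -> pseudogene (LoF
    dominates even near a border); no LoF but the region's flank extension
    was clipped by a scaffold end on the incomplete side -> edge; otherwise
    truncated.
    """
    if _AMBIG_RE.search(cds_nt):
        return "ambiguous"
    if not lof and cds_is_intact(cds_nt) and len(cds_nt) >= params.min_complete_nt:
        return "complete"
    if lof:
        return "pseudogene"
    if border_clipped:
        return "edge"
    return "truncated"


# --- seven-TM screening ------------------------------------------------------

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}


def count_tm_helices(
    protein: str,
    window: int = 19,
    threshold: float = 1.6,
    min_run: int = 15,
    merge_gap: int = 5,
    tm_min: int = 6,
) -> tuple[int, bool]:
    """Transmembrane helix count from Kyte-Doolittle hydropathy.

    A TM segment is a maximal run of window centers whose mean hydropathy is
    >= ``threshold``; runs shorter than ``min_run`` are dropped and runs
    separated by fewer than ``merge_gap`` residues are merged. The GPCR
    screen passes when at least ``tm_min`` segments are found.
    """
    vals = np.array([KYTE_DOOLITTLE.get(a, 0.0) for a in protein.upper()])
    if len(vals) < window:
        return 0, False
    kernel = np.ones(window) / window
    means = np.convolve(vals, kernel, mode="valid")
    above = means >= threshold
    runs: list[tuple[int, int]] = []
    i = 0
    while i < len(above):
        if above[i]:
            j = i
            while j < len(above) and above[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    merged: list[tuple[int, int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] < merge_gap:
            merged[-1] = (merged[-1][0], run[1])
        else:
            merged.append(run)
    segments = [r for r in merged if r[1] - r[0] >= min_run]
    count = len(segments)
    return count, count >= tm_min


# --- single-exon mining ------------------------------------------------------


def mine_single_exon(
    genome: Genome,
    family: str,
    refdb: ReferenceDB,
    params: FamilyParams | None = None,
    external_hits: list[TranslatedHit] | None = None,
) -> list[GeneCandidate]:
    """Full single-exon mining pipeline for one family.

    Round 1 finds complete genes (search -> best-hit regions -> 1 kb flanks
    -> ORFs of at least the family minimum -> family assignment). Round 2
    rescans at e <= 1e-20 with the completes and the family references as
    queries, masks regions already owned by complete genes, and classifies
    the remaining loci as pseudogene / truncated / edge / ambiguous.
    """
    params = params or default_family_params(family, "single")
    if params.exon_mode != "single":
        raise ValueError("mine_single_exon requires single-exon params")
    queries = {r.ref_id: r.protein for r in refdb.queries(family)}
    if not queries:
        raise ValueError(f"no family_query references for {family}")
    hits = external_hits
    if hits is None:
        hits = seqcore.translated_search(queries, genome, params.search_evalue)
    regions = seqcore.merge_best_hit_regions(hits)
    extended = seqcore.extend_intervals(regions, params.flank_bp, genome)

    completes: list[GeneCandidate] = []
    for ext in extended:
        completes.extend(
            _complete_candidates_in_region(genome, ext, family, refdb, params)
        )

    # round 2: stringent rescan seeded with the completes themselves
    queries2 = dict(queries)
    for i, cand in enumerate(completes):
        queries2[f"__complete_{i}"] = cand.protein
    hits2 = seqcore.translated_search(queries2, genome, params.rescan_evalue)
    complete_spans = [c.model.span for c in completes]
    hits2 = [
        h for h in hits2
        if not any(h.interval.overlaps(s) for s in complete_spans)
    ]
    protein_of = dict(queries2)
    incompletes: list[GeneCandidate] = []
    regions2 = seqcore.merge_best_hit_regions(hits2)
    extended2 = seqcore.extend_intervals(regions2, params.flank_bp, genome)
    for ext in extended2:
        cand = _incomplete_candidate_in_region(
            genome, ext, hits2, protein_of, family, refdb, params
        )
        if cand is not None:
            incompletes.append(cand)
    return completes + incompletes


def _complete_candidates_in_region(
    genome: Genome,
    ext: ExtendedRegion,
    family: str,
    refdb: ReferenceDB,
    params: FamilyParams,
) -> list[GeneCandidate]:
    orfs = seqcore.find_orfs(
        genome, ext.interval, params.min_complete_nt, params.require_start
    )
    scored = []
    for orf in orfs:
        if not orf.has_stop:
            continue
        fam, ref_id, score = classify_family(
            orf.aa, refdb, params.classify_min_score
        )
        if fam == family:
            scored.append((orf, ref_id, score))
    scored.sort(key=lambda t: (-t[2], t[0].interval.start))
    out: list[GeneCandidate] = []
    for orf, ref_id, score in scored:
        if any(orf.interval.overlaps(c.model.span) for c in out):
            continue
        status = assign_status(orf.nt, [], border_clipped=False, params=params)
        tm_count, tm_pass = count_tm_helices(orf.aa, tm_min=params.tm_min)
        out.append(
            GeneCandidate(
                family=family,
                model=GeneModel([orf.interval], orf.nt, score, ref_id),
                status=status,
                lof=[],
                tm_count=tm_count,
                tm_pass=tm_pass,
                best_ref_id=ref_id,
                best_ref_identity=protein_identity(orf.aa, refdb[ref_id].protein),
                clipped_start=ext.clipped_start,
                clipped_end=ext.clipped_end,
                protein=orf.aa,
            )
        )
    return out


def _incomplete_candidate_in_region(
    genome: Genome,
    ext: ExtendedRegion,
    hits: list[TranslatedHit],
    protein_of: dict[str, str],
    family: str,
    refdb: ReferenceDB,
    params: FamilyParams,
) -> GeneCandidate | None:
    region_hits = [h for h in hits if h.interval.overlaps(ext.interval)]
    if not region_hits:
        return None
    best = min(
        region_hits, key=lambda h: (-h.raw_score, h.interval.start, h.query_id)
    )
    strand = best.interval.strand
    ref_protein = protein_of[best.query_id]
    oriented = genome.fetch(
        GenomicInterval(
            ext.interval.scaffold_id, ext.interval.start, ext.interval.end, strand
        )
    )
    aln = detect_lof_alignment(oriented, ref_protein, params.stop_margin)
    if aln.score < params.min_fragment_score or aln.dna_end <= aln.dna_start:
        return None
    fam, ref_id, score = classify_family(
        aln.matched_aa, refdb, params.classify_min_score
    )
    if fam != family:
        return None
    cds = oriented[aln.dna_start : aln.dna_end]
    n = ext.interval.length
    if strand == "+":
        abs_start = ext.interval.start + aln.dna_start
        abs_end = ext.interval.start + aln.dna_end
    else:
        abs_start = ext.interval.start + (n - aln.dna_end)
        abs_end = ext.interval.start + (n - aln.dna_start)
    interval = GenomicInterval(ext.interval.scaffold_id, abs_start, abs_end, strand)
    lof = [LoFEvent(kind, pos) for kind, pos in aln.events]
    ref_len = len(ref_protein.replace("*", ""))
    border_clipped = _clipped_on_incomplete_side(
        aln, ref_len, strand, ext.clipped_start, ext.clipped_end
    )
    status = assign_status(cds, lof, border_clipped, params)
    if status == "complete":
        # a second-round locus is by construction incomplete; demote
        status = "truncated"
    return GeneCandidate(
        family=family,
        model=GeneModel([interval], cds, float(aln.score), ref_id),
        status=status,
        lof=lof,
        best_ref_id=ref_id,
        best_ref_identity=protein_identity(aln.matched_aa, refdb[ref_id].protein),
        clipped_start=ext.clipped_start,
        clipped_end=ext.clipped_end,
        protein=aln.matched_aa,
    )


def _clipped_on_incomplete_side(
    aln: LofAlignment,
    ref_len: int,
    strand: str,
    clipped_start: bool,
    clipped_end: bool,
) -> bool:
    """Edge rule: the flank extension was clipped by a scaffold end on the
    side where the alignment to the best reference is incomplete."""
    missing_nterm = aln.ref_start > 0
    missing_cterm = aln.ref_end < ref_len
    if strand == "+":
        return (missing_nterm and clipped_start) or (missing_cterm and clipped_end)
    return (missing_nterm and clipped_end) or (missing_cterm and clipped_start)


# --- multi-exon mining -------------------------------------------------------


def mine_multi_exon(
    genome: Genome,
    family: str,
    refdb: ReferenceDB,
    params: FamilyParams | None = None,
    external_hits: list[TranslatedHit] | None = None,
    external_models: list[GeneModel] | None = None,
) -> list[GeneCandidate]:
    """Full multi-exon mining pipeline for one family.

    Search -> 30 kb per-hit extension and union -> exon-count inference per
    region -> spliced model prediction (or externally supplied GFF3 models)
    -> iterative selection -> LoF detection and status assignment -> family
    assignment on the LoF-removed translation -> sub-400 bp discard for the
    long families.
    """
    params = params or default_family_params(family, "multi")
    if params.exon_mode != "multi":
        raise ValueError("mine_multi_exon requires multi-exon params")
    queries = {r.ref_id: r.protein for r in refdb.queries(family)}
    if not queries:
        raise ValueError(f"no family_query references for {family}")
    hits = external_hits
    if hits is None:
        hits = seqcore.translated_search(queries, genome, params.search_evalue)
    if not hits:
        return []
    extended = seqcore.extend_intervals(
        [h.interval for h in hits], params.flank_bp, genome
    )
    candidates: list[GeneCandidate] = []
    for ext in extended:
        region_hits = [h for h in hits if h.interval.overlaps(ext.interval)]
        cap = 0
        for strand in ("+", "-"):
            spans = [
                (h.interval.start, h.interval.end)
                for h in region_hits
                if h.interval.strand == strand
            ]
            cap = max(
                cap,
                infer_exon_count(
                    spans, params.exon_hit_min_bp, params.exon_gap_min_bp
                ),
            )
        if cap == 0:
            continue
        if external_models is not None:
            preds = [
                m for m in external_models if m.span.overlaps(ext.interval)
            ]
        else:
            preds = []
            for ref_id, prot in queries.items():
                preds.extend(
                    predict_gene_models(genome, ext.interval, prot, params, ref_id)
                )
        accepted = select_gene_models(preds, cap, params)
        for model in accepted:
            cand = _candidate_from_model(model, ext, queries, family, refdb, params)
            if cand is not None:
                candidates.append(cand)
    candidates.sort(key=lambda c: (c.model.span.scaffold_id, c.model.span.start))
    return candidates


def _candidate_from_model(
    model: GeneModel,
    ext: ExtendedRegion,
    queries: dict[str, str],
    family: str,
    refdb: ReferenceDB,
    params: FamilyParams,
) -> GeneCandidate | None:
    if params.min_report_nt and len(model.cds_nt) < params.min_report_nt:
        return None
    ref_protein = queries.get(model.ref_id or "", next(iter(queries.values())))
    aln = detect_lof_alignment(model.cds_nt, ref_protein, params.stop_margin)
    if aln.score < params.min_fragment_score:
        return None
    # family assignment on the translated model, LoF mutations removed first
    fam, ref_id, score = classify_family(
        aln.matched_aa, refdb, params.classify_min_score
    )
    if fam != family:
        return None
    lof = [LoFEvent(kind, pos) for kind, pos in aln.events]
    ref_len = len(ref_protein.replace("*", ""))
    border_clipped = _clipped_on_incomplete_side(
        aln, ref_len, model.strand, ext.clipped_start, ext.clipped_end
    )
    status = assign_status(model.cds_nt, lof, border_clipped, params)
    tm_count = tm_pass = None
    if status == "complete":
        aa = decode_protein(translate_codes(encode_dna(model.cds_nt), 0)).rstrip("*")
        tm_count, tm_pass = count_tm_helices(aa, tm_min=params.tm_min)
    return GeneCandidate(
        family=family,
        model=model,
        status=status,
        lof=lof,
        tm_count=tm_count,
        tm_pass=tm_pass,
        best_ref_id=ref_id,
        best_ref_identity=protein_identity(aln.matched_aa, refdb[ref_id].protein),
        clipped_start=ext.clipped_start,
        clipped_end=ext.clipped_end,
        protein=aln.matched_aa,
    )


def mine_family(
    genome: Genome,
    family: str,
    refdb: ReferenceDB,
    params: FamilyParams | None = None,
    **kwargs,
) -> list[GeneCandidate]:
    """Dispatch to the single- or multi-exon procedure for one family."""
    params = params or default_family_params(family)
    if params.exon_mode == "single":
        return mine_single_exon(genome, family, refdb, params, **kwargs)
    return mine_multi_exon(genome, family, refdb, params, **kwargs)


# --- contamination screen ----------------------------------------------------


def screen_contamination(
    candidates: dict[str, str],
    foreign_db: dict[str, str],
    max_evalue: float = 10.0,
    flag_identity: float = 0.90,
) -> pd.DataFrame:
    """Screen candidate CDSs against a foreign nucleotide database.

    Candidates with at least one nucleotide-level match at
    E <= ``max_evalue`` are reported with their best foreign hit and the
    identity of the pairwise coding alignment (proteins aligned, identity
    computed on the aligned columns — the align-then-reverse-translate
    recipe); identities above ``flag_identity`` are flagged as suspect
    contamination.
    """
    m_total = sum(len(s) for s in candidates.values())
    n_total = sum(len(s) for s in foreign_db.values())
    rows = []
    enc_foreign = {fid: encode_dna(s) for fid, s in foreign_db.items()}
    for cid, cseq in candidates.items():
        cenc = encode_dna(cseq)
        best = None
        for fid, fenc in enc_foreign.items():
            for seg in nt_seed_segments(cenc, fenc):
                ev = _ka_evalue(
                    seg.score, m_total, n_total, NT_KA_LAMBDA, NT_KA_K
                )
                if ev <= max_evalue and (best is None or seg.score > best[0]):
                    best = (seg.score, fid, ev)
        if best is None:
            continue
        _, fid, ev = best
        ident = coding_identity(cseq, foreign_db[fid])
        rows.append(
            dict(
                candidate=cid,
                foreign_best_hit=fid,
                evalue=ev,
                identity=ident,
                suspect=ident > flag_identity,
            )
        )
    return pd.DataFrame(
        rows, columns=["candidate", "foreign_best_hit", "evalue", "identity", "suspect"]
    )


# --- candidate output --------------------------------------------------------


def write_candidates_fasta(
    candidates: list[GeneCandidate], cds_path: str | Path, protein_path: str | Path
) -> None:
    with open(cds_path, "w") as cf, open(protein_path, "w") as pf:
        for i, c in enumerate(candidates):
            name = f"{c.family}_{i}_{c.status}"
            cf.write(f">{name}\n{c.model.cds_nt}\n")
            if c.protein:
                pf.write(f">{name}\n{c.protein}\n")


def write_candidates_gff3(
    candidates: list[GeneCandidate], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, c in enumerate(candidates):
            span = c.model.span
            lof = ",".join(e.key for e in c.lof) or "none"
            attrs = (
                f"ID={c.family}_{i};status={c.status};lof={lof};"
                f"best_ref={c.best_ref_id}"
            )
            fh.write(
                f"{span.scaffold_id}\tchemomine\tgene\t{span.start + 1}\t"
                f"{span.end}\t{c.model.score:.1f}\t{span.strand}\t.\t{attrs}\n"
            )
            for j, e in enumerate(c.model.exons):
                fh.write(
                    f"{e.scaffold_id}\tchemomine\texon\t{e.start + 1}\t{e.end}\t"
                    f".\t{e.strand}\t.\tID={c.family}_{i}.e{j};"
                    f"Parent={c.family}_{i}\n"
                )
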