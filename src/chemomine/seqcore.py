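"""Sequence and interval primitives.

Genome FASTA handling, six-frame translation, ORF finding, a built-in
translated homology search (with an import path for externally produced
12-column tabular hits), best-hit region merging and flank extension.

Coordinates are 0-based half-open everywhere. Minus-strand features are
stored in forward coordinates with a strand flag; the coding sequence of a
minus-strand feature is the reverse complement of the forward slice.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

from ._align import (
    encode_dna,
    encode_protein,
    evalue as _ka_evalue,
    revcomp,
    seed_segments,
    translate_codes,
    decode_protein,
)

__all__ = [
    "Genome",
    "GenomicInterval",
    "TranslatedHit",
    "OrfRecord",
    "read_genome_fasta",
    "six_frame_translate",
    "find_orfs",
    "translated_search",
    "read_tabular_hits",
    "merge_best_hit_regions",
    "extend_intervals",
    "write_bed",
]

_VALID_NT = set("ACGTNRYSWKMBDHV")

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Scaffold-anchored, stranded coordinate span (0-based half-open)."""

    scaffold_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.scaffold_id}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Strand-agnostic overlap on the same scaffold."""
        return (
            self.scaffold_id == other.scaffold_id
            and self.start < other.end
            and other.start < self.end
        )


class Genome:
    """Ordered map of scaffold id to uppercased IUPAC nucleotide string."""

    def __init__(self, scaffolds: dict[str, str]):
        if not scaffolds:
            raise ValueError("genome must contain at least one scaffold")
        clean: dict[str, str] = {}
        for sid, seq in scaffolds.items():
            seq = seq.upper()
            if not seq:
                raise ValueError(f"scaffold {sid!r} is empty")
            bad = set(seq) - _VALID_NT
            if bad:
                raise ValueError(f"scaffold {sid!r} has invalid characters {bad}")
            clean[sid] = seq
        self.scaffolds = clean

    def __contains__(self, sid: str) -> bool:
        return sid in self.scaffolds

    def __getitem__(self, sid: str) -> str:
        return self.scaffolds[sid]

    def length(self, sid: str) -> int:
        return len(self.scaffolds[sid])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.scaffolds.values())

    def _check(self, interval: GenomicInterval) -> None:
        if interval.scaffold_id not in self.scaffolds:
            raise KeyError(f"unknown scaffold {interval.scaffold_id!r}")
        if interval.end > self.length(interval.scaffold_id):
            raise ValueError(
                f"interval {interval} exceeds scaffold length "
                f"{self.length(interval.scaffold_id)}"
            )

    def slice(self, interval: GenomicInterval) -> str:
        """Forward-strand slice regardless of the interval's strand flag."""
        self._check(interval)
        return self.scaffolds[interval.scaffold_id][interval.start : interval.end]

    def fetch(self, interval: GenomicInterval) -> str:
        """Oriented sequence: reverse complement for minus-strand intervals."""
        seq = self.slice(interval)
        return revcomp(seq) if interval.strand == "-" else seq

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for sid, seq in self.scaffolds.items():
                fh.write(f">{sid}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


@dataclass(frozen=True)
class TranslatedHit:
    """One local protein-vs-translated-genome alignment."""

    query_id: str
    interval: GenomicInterval
    frame: int  # 1..3 relative to the hit strand
    raw_score: float
    evalue: float
    identity: float

    def __post_init__(self):
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError("identity must be in [0, 1]")


@dataclass(frozen=True)
class OrfRecord:
    """Open reading frame: CDS (incl. terminal stop codon when present)."""

    interval: GenomicInterval
    nt: str
    aa: str
    has_start: bool
    has_stop: bool


def read_genome_fasta(path: str | Path) -> Genome:
    """Load a (multi-)FASTA genome; duplicate record ids are rejected."""
    path = Path(path)
    scaffolds: dict[str, str] = {}
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in scaffolds:
                raise ValueError(f"duplicate scaffold id {rec.id!r} in {path}")
            scaffolds[rec.id] = str(rec.seq).upper()
    if not scaffolds:
        raise ValueError(f"no FASTA records found in {path}")
    return Genome(scaffolds)


def read_protein_fasta(path: str | Path) -> dict[str, str]:
    """Protein FASTA to an ordered id -> sequence map (duplicates rejected)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in out:
                raise ValueError(f"duplicate protein id {rec.id!r} in {path}")
            out[rec.id] = str(rec.seq).upper()
    return out


def six_frame_translate(dna: str) -> dict[tuple[str, int], str]:
    """Translate all six frames; keys are (strand, frame 1..3).

    Stops render '*'; codons containing ambiguity codes render 'X';
    trailing partial codons are dropped.
    """
    if not dna:
        raise ValueError("cannot translate an empty sequence")
    out: dict[tuple[str, int], str] = {}
    for strand, seq in (("+", dna), ("-", revcomp(dna))):
        codes = encode_dna(seq)
        for frame in range(3):
            out[(strand, frame + 1)] = decode_protein(translate_codes(codes, frame))
    return out


def _orf_spans(codes: np.ndarray, frame: int, min_len_nt: int,
               require_start: bool) -> list[tuple[int, int, bool, bool]]:
    """ORF spans (local nt start, end, has_start, has_stop) in one frame."""
    aa = translate_codes(codes, frame)
    if len(aa) == 0:
        return []
    from ._align import STOP_CODE, AA_INDEX

    stops = np.nonzero(aa == STOP_CODE)[0]
    met = AA_INDEX["M"]
    spans = []
    seg_start = 0
    bounds = list(stops) + [len(aa)]
    for b in bounds:
        has_stop = b < len(aa)
        seg = aa[seg_start:b]
        if len(seg) > 0:
            if require_start:
                starts = np.nonzero(seg == met)[0]
                first = int(starts[0]) + seg_start if len(starts) else None
            else:
                first = seg_start
            if first is not None:
                end_codon = b + 1 if has_stop else b
                nt_start = frame + 3 * first
                nt_end = frame + 3 * end_codon
                if nt_end - nt_start >= min_len_nt:
                    spans.append((nt_start, nt_end, True if require_start else
                                  bool(aa[first] == met), has_stop))
        seg_start = b + 1
    return spans


def find_orfs(
    genome: Genome,
    region: GenomicInterval,
    min_len_nt: int,
    require_start: bool = True,
) -> list[OrfRecord]:
    """Scan all six frames of a region for ORFs of at least min_len_nt.

    In start-anchored mode an ORF runs from the first ATG after a stop to the
    next stop codon (the longest ORF per stop-bounded segment, as in getorf);
    in stop-to-stop mode the whole stop-bounded span is reported. The length
    threshold counts the terminal stop codon when present. Coordinates are on
    the forward strand of the parent scaffold.
    """
    if min_len_nt < 3:
        raise ValueError("min_len_nt must be >= 3")
    seq = genome.slice(region)
    n = len(seq)
    records: list[OrfRecord] = []
    for strand in ("+", "-"):
        oriented = seq if strand == "+" else revcomp(seq)
        codes = encode_dna(oriented)
        for frame in range(3):
            for s, e, has_start, has_stop in _orf_spans(
                codes, frame, min_len_nt, require_start
            ):
                if strand == "+":
                    abs_start = region.start + s
                    abs_end = region.start + e
                else:
                    abs_start = region.start + (n - e)
                    abs_end = region.start + (n - s)
                iv = GenomicInterval(region.scaffold_id, abs_start, abs_end, strand)
                nt = oriented[s:e]
                aa = decode_protein(translate_codes(encode_dna(nt), 0))
                if has_stop:
                    aa = aa[:-1]
                records.append(OrfRecord(iv, nt, aa, has_start, has_stop))
    records.sort(key=lambda r: (r.interval.start, r.interval.end, r.interval.strand))
    return records


def translated_search(
    ref_proteins: dict[str, str] | list[tuple[str, str]],
    genome: Genome,
    max_evalue: float = 1e-5,
) -> list[TranslatedHit]:
    """Search protein queries against all six frames of a genome.

    Returns hits with E-value <= max_evalue, sorted by
    (scaffold, start, -score). The search space for the E-value is
    (sum of query lengths) x (sum of scaffold lengths).
    """
    if isinstance(ref_proteins, dict):
        queries = list(ref_proteins.items())
    else:
        queries = list(ref_proteins)
    if not queries:
        raise ValueError("at least one reference protein is required")
    if max_evalue <= 0:
        raise ValueError("max_evalue must be positive")
    from ._align import TargetKmerIndex, build_query_kmer_map

    m_total = sum(len(p) for _, p in queries)
    n_total = genome.total_length
    enc_queries = []
    for qid, p in queries:
        qc = encode_protein(p.replace("*", ""))
        enc_queries.append((qid, qc, build_query_kmer_map(qc)))
    hits: list[TranslatedHit] = []
    # translated frames and their k-mer indexes are cached on the genome so
    # repeated searches (families, rescan rounds) share the work
    cache = getattr(genome, "_frame_cache", None)
    if cache is None:
        cache = {}
        genome._frame_cache = cache  # type: ignore[attr-defined]
    for sid, seq in genome.scaffolds.items():
        slen = len(seq)
        for strand in ("+", "-"):
            for frame in range(3):
                key = (sid, strand, frame)
                if key not in cache:
                    oriented = seq if strand == "+" else revcomp(seq)
                    codes = encode_dna(oriented)
                    target = translate_codes(codes, frame)
                    cache[key] = (
                        target,
                        TargetKmerIndex(target) if len(target) else None,
                    )
                target, index = cache[key]
                if index is None:
                    continue
                for qid, qc, qmap in enc_queries:
                    for seg in seed_segments(
                        qc, target, qmap=qmap, target_index=index
                    ):
                        ev = _ka_evalue(seg.score, m_total, n_total)
                        if ev > max_evalue:
                            continue
                        nt_s = frame + 3 * seg.t_start
                        nt_e = frame + 3 * seg.t_end
                        if strand == "+":
                            a, b = nt_s, nt_e
                        else:
                            a, b = slen - nt_e, slen - nt_s
                        hits.append(
                            TranslatedHit(
                                qid,
                                GenomicInterval(sid, a, b, strand),
                                frame + 1,
                                float(seg.score),
                                ev,
                                seg.identity,
                            )
                        )
    hits.sort(key=lambda h: (h.interval.scaffold_id, h.interval.start, -h.raw_score))
    return hits


def read_tabular_hits(path: str | Path, genome: Genome) -> list[TranslatedHit]:
    """Import externally produced 12-column tabular homology hits.

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore. Subject coordinates are 1-based inclusive;
    sstart > send encodes a minus-strand hit.
    """
    hits: list[TranslatedHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(parts)}"
                )
            try:
                qid, sid = parts[0], parts[1]
                pident = float(parts[2])
                sstart, send = int(parts[8]), int(parts[9])
                ev = float(parts[10])
                bitscore = float(parts[11])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if sid not in genome:
                raise ValueError(f"{path}:{lineno}: unknown scaffold {sid!r}")
            if sstart <= send:
                strand, start, end = "+", sstart - 1, send
            else:
                strand, start, end = "-", send - 1, sstart
            slen = genome.length(sid)
            if strand == "+":
                frame = start % 3 + 1
            else:
                frame = (slen - end) % 3 + 1
            hits.append(
                TranslatedHit(
                    qid,
                    GenomicInterval(sid, start, end, strand),
                    frame,
                    bitscore,
                    ev,
                    pident / 100.0,
                )
            )
    hits.sort(key=lambda h: (h.interval.scaffold_id, h.interval.start, -h.raw_score))
    return hits


def merge_best_hit_regions(hits: list[TranslatedHit]) -> list[GenomicInterval]:
    """Non-overlapping best-hit regions.

    Hits are clustered by transitive overlap per scaffold (strand-agnostic);
    each cluster contributes the interval of its single highest-scoring hit.
    Ties break by (score desc, start asc, query_id lexicographic).
    """
    by_scaffold: dict[str, list[TranslatedHit]] = {}
    for h in hits:
        by_scaffold.setdefault(h.interval.scaffold_id, []).append(h)
    regions: list[GenomicInterval] = []
    for sid in sorted(by_scaffold):
        shits = sorted(by_scaffold[sid], key=lambda h: h.interval.start)
        cluster: list[TranslatedHit] = []
        cluster_end = -1
        for h in shits:
            if cluster and h.interval.start >= cluster_end:
                regions.append(_best_hit(cluster).interval)
                cluster = []
                cluster_end = -1
            cluster.append(h)
            cluster_end = max(cluster_end, h.interval.end)
        if cluster:
            regions.append(_best_hit(cluster).interval)
    regions.sort(key=lambda iv: (iv.scaffold_id, iv.start))
    return regions


def _best_hit(cluster: list[TranslatedHit]) -> TranslatedHit:
    return min(
        cluster,
        key=lambda h: (-h.raw_score, h.interval.start, h.query_id),
    )


@dataclass(frozen=True)
class ExtendedRegion:
    interval: GenomicInterval
    clipped_start: bool
    clipped_end: bool


def extend_intervals(
    intervals: list[GenomicInterval],
    flank_bp: int,
    genome: Genome,
) -> list[ExtendedRegion]:
    """Widen each interval by flank_bp, clip at scaffold bounds, re-merge.

    Overlapping (or touching) extended intervals are unioned so downstream
    regions are non-overlapping; clip flags mark truncation by a scaffold
    end on the corresponding side. Union regions are reported on '+'.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    wanted: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        if iv.scaffold_id not in genome:
            raise KeyError(f"unknown scaffold {iv.scaffold_id!r}")
        wanted.setdefault(iv.scaffold_id, []).append(
            (iv.start - flank_bp, iv.end + flank_bp)
        )
    out: list[ExtendedRegion] = []
    for sid in sorted(wanted):
        slen = genome.length(sid)
        spans = sorted(wanted[sid])
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if max(s, 0) < min(cur_e, slen):
                # overlap in clipped coordinates -> union of desired spans
                cur_e = max(cur_e, e)
                cur_s = min(cur_s, s)
            else:
                out.append(_clip(sid, cur_s, cur_e, slen))
                cur_s, cur_e = s, e
        out.append(_clip(sid, cur_s, cur_e, slen))
    out.sort(key=lambda r: (r.interval.scaffold_id, r.interval.start))
    return out


def _clip(sid: str, desired_start: int, desired_end: int, slen: int) -> ExtendedRegion:
    s = max(desired_start, 0)
    e = min(desired_end, slen)
    return ExtendedRegion(
        GenomicInterval(sid, s, e, "+"),
        clipped_start=desired_start < 0,
        clipped_end=desired_end > slen,
    )


def write_bed(intervals: list[GenomicInterval], path: str | Path,
              names: list[str] | None = None) -> None:
    """Dump intervals as BED6 (score column 0)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names else f"region{i}"
            fh.write(
                f"{iv.scaffold_id}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n"
            )
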