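"""Internal alignment engine.

Fast numpy six-frame translation and a seed-and-extend local aligner used by
the translated homology search. Seeds are exact amino-acid k-mers shared
between query and translated target; each seed is extended without gaps in
both directions under BLOSUM62 with an X-drop rule. Significance is assessed
with a Karlin-Altschul style E-value using fixed ungapped parameters
(lambda = 0.267, K = 0.041). The contract is recall on planted genes and
monotonicity of E in score, not equivalence to any external search tool.

Exact protein-protein local alignment (family assignment, identity
computations) goes through Bio.Align.PairwiseAligner with the same scoring
scheme (BLOSUM62, gap open -11 / extend -1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.CodonTable import standard_dna_table

# Amino-acid alphabet; order matches the BLOSUM62 matrix shipped with biopython.
AA_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}
X_CODE = AA_INDEX["X"]
STOP_CODE = AA_INDEX["*"]

# Karlin-Altschul parameters (ungapped BLOSUM62 defaults) for protein search.
KA_LAMBDA = 0.267
KA_K = 0.041

# Nucleotide scoring for the contamination screen (match +2 / mismatch -3).
NT_KA_LAMBDA = 0.625
NT_KA_K = 0.41

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn", "TGCAYRSWMKVHDBNtgcayrswmkvhdbn"
)


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware."""
    return seq.translate(_COMPLEMENT)[::-1]


@lru_cache(maxsize=1)
def blosum62_array() -> np.ndarray:
    """BLOSUM62 as a 24x24 int array indexed by AA_ALPHABET codes."""
    mat = substitution_matrices.load("BLOSUM62")
    arr = np.zeros((len(AA_ALPHABET), len(AA_ALPHABET)), dtype=np.int32)
    for i, a in enumerate(AA_ALPHABET):
        for j, b in enumerate(AA_ALPHABET):
            arr[i, j] = int(mat[a, b])
    return arr


_AA_ENCODE_TABLE = np.full(256, X_CODE, dtype=np.uint8)
for _aa, _i in AA_INDEX.items():
    _AA_ENCODE_TABLE[ord(_aa)] = _i
    _AA_ENCODE_TABLE[ord(_aa.lower())] = _i


def encode_protein(seq: str) -> np.ndarray:
    """Encode a protein string to alphabet codes; unknown letters become X."""
    return _AA_ENCODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


# --- numpy translation -------------------------------------------------------

_NT_CODE = np.full(256, 4, dtype=np.uint8)  # 4 = ambiguous / non-ACGT
for _i, _nt in enumerate("ACGT"):
    _NT_CODE[ord(_nt)] = _i
    _NT_CODE[ord(_nt.lower())] = _i


@lru_cache(maxsize=1)
def _codon_aa_codes() -> np.ndarray:
    """aa code for each of the 64 codons (index = 16*a + 4*b + c)."""
    table = standard_dna_table
    out = np.empty(64, dtype=np.uint8)
    nts = "ACGT"
    for i, a in enumerate(nts):
        for j, b in enumerate(nts):
            for k, c in enumerate(nts):
                codon = a + b + c
                if codon in table.stop_codons:
                    aa = "*"
                else:
                    aa = table.forward_table[codon]
                out[16 * i + 4 * j + k] = AA_INDEX[aa]
    return out


def encode_dna(seq: str) -> np.ndarray:
    return _NT_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def translate_codes(nt_codes: np.ndarray, frame: int = 0) -> np.ndarray:
    """Translate encoded DNA in one frame to aa codes.

    Codons containing any non-ACGT base translate to X; stops are '*'.
    Trailing partial codons are dropped.
    """
    sub = nt_codes[frame:]
    n = (len(sub) // 3) * 3
    if n == 0:
        return np.empty(0, dtype=np.uint8)
    c = sub[:n].reshape(-1, 3).astype(np.int32)
    ambiguous = (c >= 4).any(axis=1)
    idx = 16 * c[:, 0] + 4 * c[:, 1] + c[:, 2]
    idx[ambiguous] = 0
    aa = _codon_aa_codes()[idx]
    aa[ambiguous] = X_CODE
    return aa


def decode_protein(codes: np.ndarray) -> str:
    return "".join(AA_ALPHABET[c] for c in codes)


def translate_dna(seq: str, frame: int = 0) -> str:
    return decode_protein(translate_codes(encode_dna(seq), frame))


# --- seed and extend ---------------------------------------------------------


@dataclass(frozen=True)
class Segment:
    """Ungapped local alignment segment between query and target."""

    q_start: int
    q_end: int
    t_start: int
    t_end: int
    score: int
    identity: float


def _kmer_hashes(codes: np.ndarray, k: int) -> np.ndarray:
    if len(codes) < k:
        return np.empty(0, dtype=np.int64)
    h = np.zeros(len(codes) - k + 1, dtype=np.int64)
    for j in range(k):
        h = (h << 5) | codes[j : len(codes) - k + 1 + j].astype(np.int64)
    return h


def build_query_kmer_map(query: np.ndarray, k: int = 5) -> dict[int, list[int]]:
    qmap: dict[int, list[int]] = {}
    for pos, h in enumerate(_kmer_hashes(query, k).tolist()):
        qmap.setdefault(h, []).append(pos)
    return qmap


class TargetKmerIndex:
    """Sorted k-mer hash index over a translated target for fast seeding."""

    def __init__(self, target: np.ndarray, k: int = 5):
        self.k = k
        hashes = _kmer_hashes(target, k)
        self.order = np.argsort(hashes, kind="stable")
        self.sorted_hashes = hashes[self.order]

    def matches(self, qmap: dict[int, list[int]]) -> list[tuple[int, int]]:
        """(tpos, qpos) pairs for every shared k-mer, in deterministic order."""
        keys = np.fromiter(qmap.keys(), dtype=np.int64, count=len(qmap))
        lo = np.searchsorted(self.sorted_hashes, keys, "left")
        hi = np.searchsorted(self.sorted_hashes, keys, "right")
        out: list[tuple[int, int]] = []
        for key, a, b in zip(keys.tolist(), lo.tolist(), hi.tolist()):
            if b > a:
                qpos_list = qmap[key]
                for tpos in self.order[a:b].tolist():
                    for qpos in qpos_list:
                        out.append((tpos, qpos))
        out.sort()
        return out


def seed_segments(
    query: np.ndarray,
    target: np.ndarray,
    k: int = 5,
    xdrop: int = 18,
    min_score: int = 30,
    submat: np.ndarray | None = None,
    qmap: dict[int, list[int]] | None = None,
    target_index: "TargetKmerIndex | None" = None,
) -> list[Segment]:
    """All distinct ungapped segments seeded by exact k-mer matches.

    ``qmap`` and ``target_index`` may be precomputed (with the same k) and
    shared across calls to avoid re-hashing.
    """
    if submat is None:
        submat = blosum62_array()
    if len(query) < k or len(target) < k:
        return []
    if qmap is None:
        qmap = build_query_kmer_map(query, k)
    if target_index is None:
        target_index = TargetKmerIndex(target, k)
    covered: dict[int, list[tuple[int, int]]] = {}
    segments: list[Segment] = []
    nq, nt = len(query), len(target)
    for tpos, qpos in target_index.matches(qmap):
        diag = tpos - qpos
        done = False
        for ts, te in covered.get(diag, ()):
            if ts <= tpos < te:
                done = True
                break
        if done:
            continue
        # extend right from seed start
        score = 0
        best = 0
        qi, ti = qpos, tpos
        best_q, best_t = qpos, tpos
        while qi < nq and ti < nt:
            score += submat[query[qi], target[ti]]
            if score > best:
                best, best_q, best_t = score, qi + 1, ti + 1
            if score < best - xdrop:
                break
            qi += 1
            ti += 1
        right_score = best
        q_end, t_end = best_q, best_t
        # extend left from seed start
        score = 0
        best = 0
        qi, ti = qpos - 1, tpos - 1
        best_q, best_t = qpos, tpos
        while qi >= 0 and ti >= 0:
            score += submat[query[qi], target[ti]]
            if score > best:
                best, best_q, best_t = score, qi, ti
            if score < best - xdrop:
                break
            qi -= 1
            ti -= 1
        total = right_score + best
        q_start, t_start = best_q, best_t
        covered.setdefault(diag, []).append((t_start, t_end))
        if total >= min_score and q_end > q_start:
            matches = int(
                np.sum(query[q_start:q_end] == target[t_start:t_end])
            )
            segments.append(
                Segment(
                    q_start,
                    q_end,
                    t_start,
                    t_end,
                    int(total),
                    matches / (q_end - q_start),
                )
            )
    return segments


def evalue(score: float, m: int, n: int, lam: float = KA_LAMBDA, k: float = KA_K) -> float:
    """Karlin-Altschul expectation for a raw score in an m x n search space."""
    return k * m * n * math.exp(-lam * score)


def min_significant_score(max_evalue: float, m: int, n: int,
                          lam: float = KA_LAMBDA, k: float = KA_K) -> int:
    """Smallest integer raw score with E-value <= max_evalue."""
    if max_evalue <= 0:
        raise ValueError("max_evalue must be positive")
    return max(1, math.ceil(math.log(k * m * n / max_evalue) / lam))


# --- exact protein-protein alignment ----------------------------------------


@lru_cache(maxsize=1)
def protein_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aligner.mode = "local"
    return aligner


def _clean_protein(seq: str) -> str:
    return "".join(c if c in AA_INDEX else "X" for c in seq.upper().replace("*", ""))


def protein_score(a: str, b: str) -> float:
    """Exact local Smith-Waterman score, BLOSUM62 open -11 / extend -1."""
    a, b = _clean_protein(a), _clean_protein(b)
    if not a or not b:
        return 0.0
    return float(protein_aligner().score(a, b))


def protein_identity(a: str, b: str) -> float:
    """Identity = matches / aligned columns of the best local alignment."""
    a, b = _clean_protein(a), _clean_protein(b)
    if not a or not b:
        return 0.0
    aln = protein_aligner().align(a, b)[0]
    counts = aln.counts()
    aligned = counts.identities + counts.mismatches + counts.gaps
    if aligned == 0:
        return 0.0
    return counts.identities / aligned


@lru_cache(maxsize=1)
def _global_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aligner.mode = "global"
    return aligner


def protein_identity_global(a: str, b: str) -> float:
    """Identity over the full-length pairwise alignment of two proteins."""
    a, b = _clean_protein(a), _clean_protein(b)
    if not a or not b:
        return 0.0
    aln = _global_aligner().align(a, b)[0]
    counts = aln.counts()
    aligned = counts.identities + counts.mismatches + counts.gaps
    if aligned == 0:
        return 0.0
    return counts.identities / aligned


# --- nucleotide seed search (contamination screen) ---------------------------


def nt_seed_segments(
    query: np.ndarray,
    target: np.ndarray,
    k: int = 11,
    match: int = 2,
    mismatch: int = -3,
    xdrop: int = 20,
    min_score: int = 22,
) -> list[Segment]:
    """Ungapped nucleotide segments via exact k-mer seeding (+2/-3 scoring)."""
    if len(query) < k or len(target) < k:
        return []
    valid_q = query < 4
    valid_t = target < 4
    sub = np.full((5, 5), mismatch, dtype=np.int32)
    np.fill_diagonal(sub, match)
    sub[4, :] = mismatch
    sub[:, 4] = mismatch

    def hashes(codes, valid):
        n = len(codes) - k + 1
        h = np.zeros(n, dtype=np.int64)
        ok = np.ones(n, dtype=bool)
        for j in range(k):
            h = (h << 2) | (codes[j : n + j].astype(np.int64) & 3)
            ok &= valid[j : n + j]
        h[~ok] = -1
        return h

    qh = hashes(query, valid_q)
    th = hashes(target, valid_t)
    qmap: dict[int, list[int]] = {}
    for pos, h in enumerate(qh.tolist()):
        if h >= 0:
            qmap.setdefault(h, []).append(pos)
    hits = np.nonzero(np.isin(th, qh[qh >= 0]))[0]
    covered: dict[int, list[tuple[int, int]]] = {}
    segments: list[Segment] = []
    nq, nt = len(query), len(target)
    for tpos in hits.tolist():
        if th[tpos] < 0:
            continue
        for qpos in qmap.get(th[tpos], ()):
            diag = tpos - qpos
            if any(ts <= tpos < te for ts, te in covered.get(diag, ())):
                continue
            score, best = 0, 0
            qi, ti = qpos, tpos
            bq, bt = qpos, tpos
            while qi < nq and ti < nt:
                score += sub[query[qi], target[ti]]
                if score > best:
                    best, bq, bt = score, qi + 1, ti + 1
                if score < best - xdrop:
                    break
                qi += 1
                ti += 1
            right = best
            q_end, t_end = bq, bt
            score, best = 0, 0
            qi, ti = qpos - 1, tpos - 1
            bq, bt = qpos, tpos
            while qi >= 0 and ti >= 0:
                score += sub[query[qi], target[ti]]
                if score > best:
                    best, bq, bt = score, qi, ti
                if score < best - xdrop:
                    break
                qi -= 1
                ti -= 1
            total = right + best
            q_start, t_start = bq, bt
            covered.setdefault(diag, []).append((t_start, t_end))
            if total >= min_score and q_end > q_start:
                matches = int(np.sum(query[q_start:q_end] == target[t_start:t_end]))
                segments.append(
                    Segment(q_start, q_end, t_start, t_end, int(total),
                            matches / (q_end - q_start))
                )
    return segments
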