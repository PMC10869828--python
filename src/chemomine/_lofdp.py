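"""Frameshift-aware alignment of candidate DNA to a reference protein.

A local dynamic program over (reference codon, nucleotide) cells. Each
reference residue may consume 3 nt (codon match, BLOSUM62-scored; in-frame
stop codons are allowed on the path and recorded), 1-2 nt (a net deletion
that is not a multiple of 3: a frameshift), 4-5 nt (a net insertion:
a frameshift), or 0 nt (whole-codon deletion, in-frame, not a LoF); whole
extra codons in the DNA are absorbed by an in-frame insertion move. The
matrix rows are vectorized with numpy; the within-row insertion move is a
prefix-max scan per frame class, so no Python-level inner loop is needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._align import (
    AA_ALPHABET,
    STOP_CODE,
    blosum62_array,
    encode_dna,
    encode_protein,
    translate_codes,
)

NEG_INF = -(10 ** 6)

# move codes in the traceback matrix
_ORIGIN, _M3, _F1, _F2, _F4, _F5, _D0, _I3 = range(8)

FRAMESHIFT_PENALTY = -15
CODON_GAP_PENALTY = -12

# a LoF event is only believed when flanked by at least this much alignment
# score on both sides; unsupported leading/trailing events (chance matches in
# flanking sequence reached by cheap frameshift hops) are trimmed away
MIN_EVENT_FLANK_SCORE = 25


@dataclass
class LofAlignment:
    """Best local codon-level alignment of a DNA candidate to a reference."""

    score: int
    ref_start: int  # 0-based codon index on the reference, inclusive
    ref_end: int  # exclusive
    dna_start: int  # 0-based nt on the candidate, inclusive
    dna_end: int  # exclusive
    matched_aa: str  # reference-aligned translation with LoF disruptions removed
    events: list[tuple[str, int]]  # (kind, 1-based reference codon position)


def align_dna_to_protein(
    dna: str, ref_protein: str, stop_margin: int = 15
) -> LofAlignment:
    """Align candidate DNA against a reference protein, collecting LoF events.

    Premature stops are reported only when they fall at least ``stop_margin``
    codons before the reference C-terminus, so natural C-terminal variation
    is not called a loss-of-function mutation.
    """
    ref = encode_protein(ref_protein.replace("*", ""))
    d = encode_dna(dna)
    R, N = len(ref), len(d)
    if R == 0 or N < 3:
        return LofAlignment(0, 0, 0, 0, 0, "", [])
    sub = blosum62_array()
    # aa code of the codon starting at every nt position (length N-2)
    codon_aa = translate_codes(d, 0)
    codon_aa_all = np.empty(N - 2, dtype=np.uint8)
    for f in range(3):
        fr = translate_codes(d, f)
        codon_aa_all[f::3] = fr[: len(codon_aa_all[f::3])]
    sub_by_pos = sub[:, codon_aa_all]  # (24, N-2): score of ref aa vs codon at t

    prev = np.zeros(N + 1, dtype=np.int32)
    moves = np.zeros((R + 1, N + 1), dtype=np.uint8)
    best_score, best_i, best_j = 0, 0, 0
    fs = FRAMESHIFT_PENALTY
    gp = CODON_GAP_PENALTY
    for i in range(1, R + 1):
        cand = np.full((6, N + 1), NEG_INF, dtype=np.int32)
        cand[0, 3:] = prev[:-3] + sub_by_pos[ref[i - 1], : N - 2]
        cand[1, 2:] = prev[:-2] + fs
        cand[2, 1:] = prev[:-1] + fs
        cand[3, 4:] = prev[:-4] + fs
        if N >= 5:
            cand[4, 5:] = prev[:-5] + fs
        cand[5, :] = prev + gp
        which = np.argmax(cand, axis=0)
        tmp = cand[which, np.arange(N + 1)]
        move_row = np.array([_M3, _F2, _F1, _F4, _F5, _D0], dtype=np.uint8)[which]
        move_row = np.where(tmp > 0, move_row, _ORIGIN).astype(np.uint8)
        tmp = np.maximum(tmp, 0)
        # within-row in-frame insertion move: cur[j] = max(tmp[j], cur[j-3]+gp)
        cur = tmp.copy()
        for r0 in range(3):
            idx = np.arange(r0, N + 1, 3)
            if len(idx) < 2:
                continue
            t = np.arange(len(idx), dtype=np.int64)
            adj = cur[idx] - t * gp
            run = np.maximum.accumulate(adj)
            new = (run + t * gp).astype(np.int32)
            improved = new > cur[idx]
            if improved.any():
                cur[idx] = np.where(improved, new, cur[idx])
                move_row[idx[improved]] = _I3
        moves[i] = move_row
        row_best = int(cur.max())
        if row_best > best_score:
            best_score = row_best
            best_i = i
            best_j = int(cur.argmax())
        prev = cur

    # traceback into an explicit path of (move, i, j, score_delta)
    path: list[tuple[int, int, int, int]] = []
    i, j = best_i, best_j
    while i > 0:
        mv = moves[i, j]
        if mv == _ORIGIN:
            break
        if mv == _M3:
            delta = int(sub_by_pos[ref[i - 1], j - 3])
            path.append((mv, i, j, delta))
            i, j = i - 1, j - 3
        elif mv == _F1:
            path.append((mv, i, j, fs))
            i, j = i - 1, j - 1
        elif mv == _F2:
            path.append((mv, i, j, fs))
            i, j = i - 1, j - 2
        elif mv == _F4:
            path.append((mv, i, j, fs))
            i, j = i - 1, j - 4
        elif mv == _F5:
            path.append((mv, i, j, fs))
            i, j = i - 1, j - 5
        elif mv == _D0:
            path.append((mv, i, j, gp))
            i = i - 1
        elif mv == _I3:
            path.append((mv, i, j, gp))
            j = j - 3
    path.reverse()
    start_i, start_j = i, j

    def is_event(step) -> bool:
        mv, ii, jj, _ = step
        if mv in (_F1, _F2, _F4, _F5):
            return True
        if mv == _M3 and codon_aa_all[jj - 3] == STOP_CODE:
            return True
        return False

    # trim events without enough flanking alignment support
    while path:
        event_pos = [k for k, step in enumerate(path) if is_event(step)]
        if not event_pos:
            break
        changed = False
        last = event_pos[-1]
        if sum(step[3] for step in path[last:]) < MIN_EVENT_FLANK_SCORE:
            path = path[:last]
            changed = True
        if path:
            event_pos = [k for k, step in enumerate(path) if is_event(step)]
            if event_pos:
                first = event_pos[0]
                if sum(step[3] for step in path[: first + 1]) < MIN_EVENT_FLANK_SCORE:
                    # drop everything up to and including the leading event
                    start_i, start_j = path[first][1], path[first][2]
                    path = path[first + 1 :]
                    changed = True
        if not changed:
            break

    if not path:
        return LofAlignment(0, 0, 0, 0, 0, "", [])
    end_i, end_j = path[-1][1], path[-1][2]
    score = int(sum(step[3] for step in path))
    events: list[tuple[str, int]] = []
    matched: list[str] = []
    for mv, ii, jj, _ in path:
        if mv == _M3:
            aa = codon_aa_all[jj - 3]
            if aa == STOP_CODE:
                if ii <= R - stop_margin:
                    events.append(("premature_stop", ii))
            else:
                matched.append(AA_ALPHABET[aa])
        elif mv in (_F1, _F2):
            events.append(("frameshift_deletion", ii))
        elif mv in (_F4, _F5):
            events.append(("frameshift_insertion", ii))
    events.sort(key=lambda e: (e[1], e[0]))
    return LofAlignment(
        score=score,
        ref_start=start_i,
        ref_end=end_i,
        dna_start=start_j,
        dna_end=end_j,
        matched_aa="".join(matched),
        events=events,
    )
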