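"""Perfect and imperfect microsatellite (SSR) detection in gene sequences.

The scan contract: for every start position ``s`` and motif length ``k`` in
the configured range, the candidate motif is the primitive word
``seq[s:s+k]``; the repeat array is compared position-by-position against
the periodic extension of that motif anchored at ``s``.  Matches score +1
and mismatches score ``-penalty`` (fixed 5); extension hard-stops before a
run of more than ``max_consecutive_mismatches`` (3) mismatch sites; the
candidate endpoint is the match position maximizing the running score
(leftmost on ties).  Candidates scoring at least ``min_score`` compete for
sequence space: highest score wins, then leftmost start, and accepted hits
never overlap.

Sequences containing ambiguous nucleotides (``N`` and IUPAC codes) yield no
hits and are flagged; any other character is an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

_ACGT = frozenset("ACGT")
_AMBIG = frozenset("NRYSWKMBDHV")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class SSRParams:
    motif_lengths: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    min_score: int = 15
    mismatch_penalty: int = 5
    max_consecutive_mismatches: int = 3

    def __post_init__(self) -> None:
        if any(k < 1 or k > 6 for k in self.motif_lengths):
            raise ValidationError("motif lengths must be in 1..6")
        if self.min_score < 1:
            raise ValidationError("min_score must be positive")


@dataclass(frozen=True)
class SSRHit:
    """One accepted microsatellite locus (1-based inclusive coordinates)."""

    seq_id: str
    motif: str  # canonical rotation
    start: int
    end: int
    n_mismatches: int
    score: int

    def __post_init__(self) -> None:
        span = self.end - self.start + 1
        matched = span - self.n_mismatches
        if self.score != matched - 5 * self.n_mismatches:
            raise ValidationError("score inconsistent with span and mismatches")
        if span < 1 or self.n_mismatches < 0:
            raise ValidationError("bad hit geometry")

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class NormalizedSSRContent:
    pair_id: str
    species: str
    ssr_bp: int
    alignment_len: int
    normalized: float = field(init=False)

    def __post_init__(self) -> None:
        if self.alignment_len <= 0:
            raise ValidationError("alignment_len must be positive")
        if self.ssr_bp < 0:
            raise ValidationError("ssr_bp must be non-negative")
        object.__setattr__(self, "normalized", self.ssr_bp / self.alignment_len)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def is_primitive(motif: str) -> bool:
    """True iff the motif is not a whole-number power of a shorter word."""
    k = len(motif)
    for d in range(1, k):
        if k % d == 0 and motif == motif[:d] * (k // d):
            return False
    return True


def canonical_rotation(motif: str) -> str:
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def canonical_motif(motif: str) -> str:
    """Canonical form under rotation and reverse complement."""
    return min(canonical_rotation(motif), canonical_rotation(reverse_complement(motif)))


def has_ambiguous(sequence: str) -> bool:
    return any(c in _AMBIG for c in sequence.upper())


def _check_alphabet(sequence: str) -> None:
    bad = set(sequence.upper()) - _ACGT - _AMBIG
    if bad:
        raise ValidationError(f"invalid characters in sequence: {sorted(bad)}")


def scan_ssrs(sequence: str, params: SSRParams = SSRParams(), seq_id: str = "") -> list[SSRHit]:
    """Scan one nucleotide sequence for SSR hits under the module contract.

    Returns accepted, mutually non-overlapping hits sorted by position.
    Ambiguous sequences return an empty list (callers flag them via
    :func:`has_ambiguous`); an empty sequence returns an empty list.
    """
    seq = sequence.upper()
    if not seq:
        return []
    _check_alphabet(seq)
    if has_ambiguous(seq):
        return []
    candidates = _candidates(seq, params)
    accepted = _resolve(candidates)
    return [
        SSRHit(
            seq_id=seq_id,
            motif=canonical_rotation(motif),
            start=s + 1,
            end=e + 1,
            n_mismatches=nm,
            score=score,
        )
        for (score, s, e, motif, nm) in sorted(accepted, key=lambda c: c[1])
    ]


def _candidates(seq: str, params: SSRParams) -> list[tuple[int, int, int, str, int]]:
    """All scoring candidates as (score, start, end, motif, n_mismatches)."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    L = len(arr)
    maxrun = params.max_consecutive_mismatches
    pen = params.mismatch_penalty
    out: list[tuple[int, int, int, str, int]] = []
    kernel = np.ones(maxrun + 1)
    for k in sorted(set(params.motif_lengths)):
        if L < k:
            continue
        for s in range(L - k + 1):
            motif = seq[s : s + k]
            if not is_primitive(motif):
                continue
            cap = 4 * params.min_score + 2 * k
            while True:
                end_cap = min(L, s + cap)
                window = arr[s:end_cap]
                reps = -(-len(window) // k)
                tiled = np.tile(arr[s : s + k], reps)[: len(window)]
                mism = window != tiled
                # hard stop at first completed run of maxrun+1 mismatches
                if len(window) > maxrun:
                    runs = np.convolve(mism.astype(np.int8), kernel, mode="valid")
                    stops = np.nonzero(runs >= maxrun + 1)[0]
                else:
                    stops = np.array([], dtype=int)
                if stops.size:
                    limit = stops[0] + maxrun  # last index inside the fatal run
                    mism = mism[: limit + 1]
                    break
                if end_cap == L:
                    break
                cap *= 2
            scores = np.cumsum(np.where(mism, -pen, 1))
            match_idx = np.nonzero(~mism)[0]
            if match_idx.size == 0:
                continue
            best_rel = match_idx[np.argmax(scores[match_idx])]
            best_score = int(scores[best_rel])
            if best_score < params.min_score:
                continue
            nm = int(mism[: best_rel + 1].sum())
            out.append((best_score, s, s + int(best_rel), motif, nm))
    return out


def _resolve(candidates: list[tuple[int, int, int, str, int]]):
    """Greedy best-score-first, leftmost-on-ties, non-overlapping selection."""
    accepted: list[tuple[int, int, int, str, int]] = []
    taken: list[tuple[int, int]] = []
    for cand in sorted(candidates, key=lambda c: (-c[0], c[1], c[2] - c[1], c[3])):
        _, s, e, _, _ = cand
        if any(s <= te and ts <= e for ts, te in taken):
            continue
        accepted.append(cand)
        taken.append((s, e))
    return accepted


def merged_ssr_bp(hits: list[SSRHit]) -> int:
    """Total bases covered by hits, overlaps merged (union of intervals)."""
    ivs = sorted((h.start, h.end) for h in hits)
    total = 0
    cur_s, cur_e = None, None
    for s, e in ivs:
        if cur_e is None or s > cur_e + 1:
            if cur_e is not None:
                total += cur_e - cur_s + 1
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s + 1
    return total


def normalized_ssr_content(
    gene_seq_a: str,
    gene_seq_b: str,
    alignment_len: int,
    pair_id: str = "",
    species: tuple[str, str] = ("a", "b"),
    params: SSRParams = SSRParams(),
) -> tuple[NormalizedSSRContent, NormalizedSSRContent]:
    """Alignment-length-normalized SSR base-pair content for both genes."""
    hits_a = scan_ssrs(gene_seq_a, params)
    hits_b = scan_ssrs(gene_seq_b, params)
    return (
        NormalizedSSRContent(pair_id, species[0], merged_ssr_bp(hits_a), alignment_len),
        NormalizedSSRContent(pair_id, species[1], merged_ssr_bp(hits_b), alignment_len),
    )


def shared_motifs(hits_a: list[SSRHit], hits_b: list[SSRHit]) -> set[str]:
    """Motifs present in both hit lists, canonical under rotation and
    reverse complement."""
    ma = {canonical_motif(h.motif) for h in hits_a}
    mb = {canonical_motif(h.motif) for h in hits_b}
    return ma & mb


def alignment_length(seq_a: str, seq_b: str) -> int:
    """Length of a simple global alignment (for synthetic tests only)."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -0.5
    aln = aligner.align(seq_a, seq_b)[0]
    return int(aln.length)
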