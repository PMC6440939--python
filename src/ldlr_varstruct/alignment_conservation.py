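"""Cysteine-anchored pairwise alignment and MSA-based conservation scoring.

Class-A repeats are short and cysteine-rich; naive global alignment can
mispair the structurally equivalent cysteines that form the conserved
disulfide pattern.  :func:`constrained_global_align` therefore accepts a
list of residue-pair anchors that are forced into the same column, and
aligns the blocks between anchors independently.

Conservation is scored per reference column as ``1 - H / H_max`` with
``H`` the Shannon entropy over the 20 amino acids (gaps excluded) and
``H_max = ln 20``, then z-normalized across the protein.  No sequence
weighting is applied: the intended inputs are redundancy-reduced sets
(e.g. one sequence per species from UniRef90).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "Alignment",
    "ConservationProfile",
    "constrained_global_align",
    "conservation_profile",
    "classify_conserved",
]

GAP_OPEN = 10.0
GAP_EXTEND = 0.5
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_blosum62 = substitution_matrices.load("BLOSUM62")


@dataclass
class Alignment:
    seq_a: str  # gapped
    seq_b: str
    anchor_pairs: list[tuple[int, int]]
    score: float

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("gapped sequences must have equal length")

    def columns(self) -> list[tuple[str, str]]:
        return list(zip(self.seq_a, self.seq_b))


@dataclass
class ConservationProfile:
    scores: np.ndarray        # z-normalized, one per reference residue
    raw_scores: np.ndarray    # 1 - H/H_max in [0, 1]
    n_sequences: int
    conserved_flags: np.ndarray
    threshold: float          # on the z scale

    def __len__(self) -> int:
        return len(self.scores)


def _make_aligner(mode: str = "global") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = _blosum62
    aligner.open_gap_score = -GAP_OPEN
    aligner.extend_gap_score = -GAP_EXTEND
    aligner.mode = mode
    return aligner


def _align_block(a: str, b: str) -> tuple[str, str, float]:
    """Globally align one inter-anchor block; either side may be empty."""
    if not a and not b:
        return "", "", 0.0
    if not a:
        return "-" * len(b), b, -(GAP_OPEN + GAP_EXTEND * (len(b) - 1))
    if not b:
        return a, "-" * len(a), -(GAP_OPEN + GAP_EXTEND * (len(a) - 1))
    aligner = _make_aligner()
    alignments = aligner.align(a, b)
    aln = alignments[0]  # all co-optimal; take the first deterministically
    return str(aln[0]), str(aln[1]), alignments.score


def constrained_global_align(seq_a: str, seq_b: str,
                             anchors: list[tuple[int, int]] | None = None
                             ) -> Alignment:
    """Global alignment with forced residue-pair equivalences.

    ``anchors`` are 1-based (i, j) pairs that must share a column; they must
    be strictly increasing in both coordinates (crossing anchors would not
    admit any alignment).  The segments between consecutive anchors are
    aligned independently with BLOSUM62 and affine gaps, so the total score
    is the sum of block scores plus the anchor-column substitution scores.
    """
    anchors = list(anchors or [])
    for (i1, j1), (i2, j2) in zip(anchors, anchors[1:]):
        if i2 <= i1 or j2 <= j1:
            raise ValueError(f"anchors must be strictly increasing, got "
                             f"({i1},{j1}) then ({i2},{j2})")
    for i, j in anchors:
        if not (1 <= i <= len(seq_a) and 1 <= j <= len(seq_b)):
            raise ValueError(f"anchor ({i},{j}) outside sequences")

    ga_parts: list[str] = []
    gb_parts: list[str] = []
    score = 0.0
    prev_i = prev_j = 0
    for i, j in anchors:
        block_a, block_b = seq_a[prev_i:i - 1], seq_b[prev_j:j - 1]
        pa, pb, s = _align_block(block_a, block_b)
        ga_parts.append(pa)
        gb_parts.append(pb)
        score += s
        ga_parts.append(seq_a[i - 1])
        gb_parts.append(seq_b[j - 1])
        score += float(_blosum62[seq_a[i - 1], seq_b[j - 1]])
        prev_i, prev_j = i, j
    pa, pb, s = _align_block(seq_a[prev_i:], seq_b[prev_j:])
    ga_parts.append(pa)
    gb_parts.append(pb)
    score += s
    return Alignment("".join(ga_parts), "".join(gb_parts), anchors, score)


def column_entropy(column: str) -> float | None:
    """Shannon entropy (nats) of one MSA column, gaps excluded.

    Returns None for a column that is all gaps.
    """
    letters = [c for c in column.upper() if c in AMINO_ACIDS]
    if not letters:
        return None
    counts: dict[str, int] = {}
    for c in letters:
        counts[c] = counts.get(c, 0) + 1
    n = len(letters)
    return -sum((k / n) * math.log(k / n) for k in counts.values())


def conservation_profile(msa: list[str], ref_index: int = 0,
                         quantile: float = 0.75) -> ConservationProfile:
    """Per-residue conservation of the reference row of an MSA.

    Columns where the reference has a gap are skipped (no conservation is
    defined off-reference).  Columns that are all-gap under the reference
    are flagged and given a raw score of NaN (excluded from normalization).
    A residue is flagged conserved if its column is invariant (raw score 1)
    or its z-score reaches the ``quantile`` quantile across the protein.
    """
    if not msa:
        raise ValueError("empty MSA")
    lengths = {len(row) for row in msa}
    if len(lengths) != 1:
        raise ValueError("MSA rows must have equal length")
    ref = msa[ref_index]
    h_max = math.log(len(AMINO_ACIDS))

    raw: list[float] = []
    for col_idx, ref_char in enumerate(ref):
        if ref_char == "-":
            continue
        column = "".join(row[col_idx] for row in msa)
        h = column_entropy(column)
        raw.append(math.nan if h is None else 1.0 - h / h_max)
    raw_arr = np.array(raw)

    valid = ~np.isnan(raw_arr)
    mu = float(np.mean(raw_arr[valid]))
    sd = float(np.std(raw_arr[valid]))
    z = np.full_like(raw_arr, np.nan)
    z[valid] = (raw_arr[valid] - mu) / sd if sd > 0 else 0.0

    threshold = float(np.nanquantile(z, quantile))
    flags = np.zeros(len(raw_arr), dtype=bool)
    flags[valid] = (raw_arr[valid] >= 1.0 - 1e-12) | (z[valid] >= threshold)
    return ConservationProfile(scores=z, raw_scores=raw_arr,
                               n_sequences=len(msa), conserved_flags=flags,
                               threshold=threshold)


def classify_conserved(profile: ConservationProfile,
                       threshold: float) -> np.ndarray:
    """Boolean per-position flags from an explicit z-score threshold."""
    valid = ~np.isnan(profile.scores)
    flags = np.zeros(len(profile.scores), dtype=bool)
    flags[valid] = profile.scores[valid] >= threshold
    return flags
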