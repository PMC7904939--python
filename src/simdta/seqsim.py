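"""Smith–Waterman local alignment and the normalized target similarity K2.

The target–target similarity between proteins i and j is the raw optimal
local-alignment score SW_ij normalized by the geometric mean of the
self-alignment scores:

    SW_ij^norm = SW_ij / sqrt(SW_ii * SW_jj)

so that self-similarity is exactly 1.  Raw scores use affine gap penalties:
a gap of length L costs ``gap_open + (L - 1) * gap_extend``.  The default
scoring (BLOSUM62, open 10, extend 0.5) follows the chemogenomics
convention used throughout the similarity-based affinity-prediction
literature; all three knobs are exposed.

Boundedness note: with the default scoring every off-diagonal normalized
score observed in practice lies in [0, 1], but the normalization does not
prove a bound of 1 for arbitrary substitution matrices; the matrix builder
clips at 1 only within floating-point tolerance and otherwise raises.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .core import SimilarityMatrix, Target

__all__ = [
    "AlignmentScoring",
    "default_scoring",
    "smith_waterman_score",
    "normalized_sw",
    "target_similarity_matrix",
]

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
# Ambiguity / rare-residue fallbacks: asparagine-or-aspartate, glutamine-or-
# glutamate, selenocysteine and pyrrolysine map to their closest standard
# residue; X is kept and scored by the matrix's own low-penalty X column.
AMBIGUITY_MAP = {"B": "D", "Z": "E", "U": "C", "O": "K"}


@dataclass(frozen=True)
class AlignmentScoring:
    """Substitution matrix plus affine gap penalties.

    ``matrix_name`` is any matrix shipped with Biopython
    (``Bio.Align.substitution_matrices``), e.g. "BLOSUM62" or "BLOSUM50".
    Penalties are positive magnitudes; ``gap_extend <= gap_open``.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def __post_init__(self):
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be nonnegative")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")
        # load eagerly so a bad name fails at construction
        object.__setattr__(self, "_matrix", substitution_matrices.load(self.matrix_name))

    @property
    def matrix(self):
        return self._matrix

    def substitution(self, a: str, b: str) -> float:
        return float(self._matrix[a, b])


def default_scoring() -> AlignmentScoring:
    return AlignmentScoring()


def sanitize_sequence(seq: str, context: str | None = None) -> str:
    """Uppercase, map ambiguity codes to standard residues, validate."""
    if not seq:
        where = f" ({context})" if context else ""
        raise ValueError(f"empty protein sequence{where}")
    seq = seq.upper()
    out = []
    mapped = set()
    for ch in seq:
        if ch in STANDARD_RESIDUES or ch == "X":
            out.append(ch)
        elif ch in AMBIGUITY_MAP:
            out.append(AMBIGUITY_MAP[ch])
            mapped.add(ch)
        else:
            where = f" ({context})" if context else ""
            raise ValueError(f"unknown residue code {ch!r} in sequence{where}")
    if mapped:
        warnings.warn(
            f"mapped ambiguity codes {sorted(mapped)} to standard residues",
            stacklevel=2,
        )
    return "".join(out)


def _aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.substitution_matrix = scoring.matrix
    # Biopython charges open_gap_score for the first gap residue and
    # extend_gap_score for each subsequent one, i.e. a length-L gap costs
    # open + (L-1)*extend in our sign convention.
    al.open_gap_score = -float(scoring.gap_open)
    al.extend_gap_score = -float(scoring.gap_extend)
    return al


def smith_waterman_score(
    a: str, b: str, scoring: AlignmentScoring | None = None
) -> float:
    """Optimal local-alignment score of two protein sequences (>= 0)."""
    scoring = scoring or default_scoring()
    a = sanitize_sequence(a)
    b = sanitize_sequence(b)
    score = float(_aligner(scoring).score(a, b))
    return max(score, 0.0)


def normalized_sw(
    a: str, b: str, scoring: AlignmentScoring | None = None
) -> float:
    """SW score normalized by the self-alignment geometric mean."""
    scoring = scoring or default_scoring()
    a = sanitize_sequence(a)
    b = sanitize_sequence(b)
    al = _aligner(scoring)
    saa = max(float(al.score(a, a)), 0.0)
    sbb = max(float(al.score(b, b)), 0.0)
    if saa <= 0.0 or sbb <= 0.0:
        raise RuntimeError(
            "self-alignment score is zero; cannot normalize "
            "(check the substitution matrix's diagonal)"
        )
    sab = max(float(al.score(a, b)), 0.0)
    return sab / math.sqrt(saa * sbb)


def target_similarity_matrix(
    targets: list[Target], scoring: AlignmentScoring | None = None
) -> SimilarityMatrix:
    """Pairwise normalized-SW matrix K2 over a target roster.

    Exploits symmetry (upper triangle only); the diagonal is exactly 1.
    """
    if not targets:
        raise ValueError("need at least one target")
    scoring = scoring or default_scoring()
    seqs = []
    for t in targets:
        try:
            seqs.append(sanitize_sequence(t.sequence, context=f"target {t.target_id!r}"))
        except ValueError as exc:
            raise ValueError(str(exc)) from exc
    al = _aligner(scoring)
    n = len(targets)
    self_scores = np.empty(n)
    for i, s in enumerate(seqs):
        self_scores[i] = max(float(al.score(s, s)), 0.0)
        if self_scores[i] <= 0.0:
            raise RuntimeError(
                f"self-alignment score of target {targets[i].target_id!r} is zero"
            )
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            sab = max(float(al.score(seqs[i], seqs[j])), 0.0)
            v = sab / math.sqrt(self_scores[i] * self_scores[j])
            if v > 1.0 + 1e-9:
                raise RuntimeError(
                    "normalized similarity exceeded 1 under the chosen "
                    f"scoring ({v:.6f}); not a valid similarity"
                )
            values[i, j] = values[j, i] = min(v, 1.0)
    return SimilarityMatrix(tuple(t.target_id for t in targets), values)
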