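"""Pairwise sequence divergence under the Kimura 2-parameter model.

The K2P model distinguishes transitions (A<->G, C<->T, rate alpha) from
transversions (all other changes, rate beta).  With P and Q the observed
proportions of transitional and transversional differences over comparable
sites, the corrected divergence is

    d = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]

Sites are compared under pairwise deletion: a column contributes to a pair
only when both sequences carry an unambiguous A/C/G/T there.  Saturated
pairs, where the logarithm's argument is non-positive, are flagged
``undefined`` rather than dropped silently — heavily diverged barcode
datasets (non-coding D-loop especially) are expected to contain them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)

# numeric base codes; anything not A/C/G/T (gaps, ambiguity) is missing
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
MISSING = 255

OK = "ok"
UNDEFINED = "undefined"
TOO_FEW_SITES = "too_few_sites"

#: minimum comparable sites for a defined distance
DEFAULT_MIN_SITES = 50


def encode_alignment(aln) -> np.ndarray:
    """uint8 matrix (n_seq x n_col); non-ACGT cells become MISSING."""
    n, L = len(aln.records), aln.length
    out = np.full((n, L), MISSING, dtype=np.uint8)
    for i, rec in enumerate(aln.records):
        arr = np.frombuffer(rec.residues.encode("ascii"), dtype=np.uint8)
        for base, code in _CODE.items():
            out[i, arr == ord(base)] = code
    return out


@dataclass(frozen=True)
class PairwiseCounts:
    """Transition/transversion counts for one sequence pair."""

    n_comparable: int
    n_transitions: int
    n_transversions: int

    def __post_init__(self):
        if self.n_transitions + self.n_transversions > self.n_comparable:
            raise ValueError("more differences than comparable sites")

    @property
    def P(self) -> float:
        return self.n_transitions / self.n_comparable if self.n_comparable else 0.0

    @property
    def Q(self) -> float:
        return self.n_transversions / self.n_comparable if self.n_comparable else 0.0


def count_substitutions(a: str, b: str) -> PairwiseCounts:
    """Count transitions and transversions between two aligned sequences.

    Columns where either sequence has a gap, N, or ambiguity code are
    excluded from the comparable-site count (pairwise deletion).
    """
    if len(a) != len(b):
        raise ValueError(f"unequal lengths: {len(a)} vs {len(b)}")
    ca = _encode_string(a)
    cb = _encode_string(b)
    return _counts_from_codes(ca, cb)


def _encode_string(s: str) -> np.ndarray:
    arr = np.frombuffer(s.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, MISSING, dtype=np.uint8)
    for base, code in _CODE.items():
        out[arr == ord(base)] = code
    return out


def _counts_from_codes(ca: np.ndarray, cb: np.ndarray) -> PairwiseCounts:
    both = (ca != MISSING) & (cb != MISSING)
    n_comp = int(both.sum())
    diff = both & (ca != cb)
    # with A=0,C=1,G=2,T=3 a mismatch is a transition iff XOR == 2
    ts = int((diff & ((ca ^ cb) == 2)).sum())
    tv = int(diff.sum()) - ts
    return PairwiseCounts(n_comp, ts, tv)


def k2p_distance(c: PairwiseCounts, min_sites: int = DEFAULT_MIN_SITES):
    """K2P divergence for one pair, returned as ``(d, status)``."""
    if c.n_comparable < min_sites:
        return math.nan, TOO_FEW_SITES
    w1 = 1.0 - 2.0 * c.P - c.Q
    w2 = 1.0 - 2.0 * c.Q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.nan, UNDEFINED
    return -0.5 * math.log(w1 * math.sqrt(w2)) + 0.0, OK  # +0.0 kills -0.0


def p_distance(c: PairwiseCounts, min_sites: int = 1):
    """Uncorrected proportion of differing comparable sites."""
    if c.n_comparable < max(min_sites, 1):
        return math.nan, TOO_FEW_SITES
    return (c.n_transitions + c.n_transversions) / c.n_comparable, OK


class DistanceMatrix:
    """Symmetric pairwise divergences with per-cell status flags.

    ``values`` holds dimensionless substitutions/site (NaN where not ok);
    reports multiply by 100 when printing percent divergences.
    """

    def __init__(self, labels, species_of, values, flags):
        self.labels = list(labels)
        self.species_of = dict(species_of)
        self.values = np.asarray(values, dtype=float)
        self.flags = np.asarray(flags, dtype=object)
        n = len(self.labels)
        if self.values.shape != (n, n) or self.flags.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(
            np.nan_to_num(self.values), np.nan_to_num(self.values.T)
        ):
            raise ValueError("distance matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        return self.labels.index(label)

    def species_vector(self):
        return [self.species_of[l] for l in self.labels]

    def defined_mask(self) -> np.ndarray:
        return self.flags == OK

    def to_long_rows(self, model: str):
        """Long-format rows (id_a, id_b, model, d, status) for TSV export."""
        rows = []
        for i in range(self.n):
            for j in range(i + 1, self.n):
                rows.append(
                    {
                        "id_a": self.labels[i],
                        "id_b": self.labels[j],
                        "model": model,
                        "d": self.values[i, j],
                        "status": self.flags[i, j],
                    }
                )
        return rows


def distance_matrix(aln, model: str = "k2p",
                    min_sites: int = DEFAULT_MIN_SITES) -> DistanceMatrix:
    """All-pairs divergence matrix for an alignment.

    ``model`` is ``"k2p"`` or ``"p"``.  Cells that cannot be computed are
    flagged (``undefined`` for saturated K2P pairs, ``too_few_sites`` for
    insufficient overlap) and left NaN.
    """
    model = model.lower()
    if model not in ("k2p", "p"):
        raise ValueError(f"unknown model {model!r}")
    codes = encode_alignment(aln)
    present = codes != MISSING
    n = codes.shape[0]
    values = np.zeros((n, n))
    flags = np.full((n, n), OK, dtype=object)
    n_undef = 0
    for i in range(n):
        rest = slice(i + 1, n)
        both = present[i] & present[rest]
        diff = both & (codes[i] != codes[rest])
        ts_mask = diff & ((codes[i] ^ codes[rest]) == 2)
        n_comp = both.sum(axis=1)
        ts = ts_mask.sum(axis=1)
        tv = diff.sum(axis=1) - ts
        for k, j in enumerate(range(i + 1, n)):
            c = PairwiseCounts(int(n_comp[k]), int(ts[k]), int(tv[k]))
            if model == "k2p":
                d, status = k2p_distance(c, min_sites=min_sites)
            else:
                d, status = p_distance(c, min_sites=1)
            values[i, j] = values[j, i] = d
            flags[i, j] = flags[j, i] = status
            if status != OK:
                n_undef += 1
    if n_undef:
        log.warning(
            "%d of %d pairs have no defined %s distance (flagged)",
            n_undef, n * (n - 1) // 2, model,
        )
    return DistanceMatrix(aln.ids, aln.species_of, values, flags)
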