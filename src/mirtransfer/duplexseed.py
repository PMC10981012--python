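"""Intermolecular duplex scoring, seed-type classification and negative
generation.

The duplex model is a deliberately simple base-pair-scoring dynamic
program rather than a nearest-neighbour thermodynamic model: pairs score
GC=+3, AU=+2, GU=+1; unpaired runs *between* pairs on either strand pay an
affine penalty (opening -2, each further nucleotide -1); dangling ends are
free.  The miRNA is read 5'->3', the site antiparallel, so site positions
decrease as miRNA positions increase.  The scorer is exact (verified
against exhaustive enumeration of non-crossing matchings in the tests) and
is pluggable: anything that returns a :class:`DuplexStructure` can stand
in for it.

Seed typing follows the standard convention: a *canonical* seed pairs
miRNA positions 2-7 or 3-8 by exact, contiguous Watson-Crick pairs; a
*non-canonical* seed may use GU wobbles and tolerate at most one bulged or
mismatched nucleotide in the window; anything else is ``other``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .records import InteractionRecord

RNA_ALPHABET = "ACGU"
_BASE_INDEX = {b: i for i, b in enumerate(RNA_ALPHABET)}
_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

#: pair scores on base-index pairs; 0 = unpairable
_PAIR_SCORE = np.zeros((4, 4), dtype=np.int64)
for _x, _y, _s in [
    ("G", "C", 3), ("C", "G", 3),
    ("A", "U", 2), ("U", "A", 2),
    ("G", "U", 1), ("U", "G", 1),
]:
    _PAIR_SCORE[_BASE_INDEX[_x], _BASE_INDEX[_y]] = _s

_WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU_PAIRS = {("G", "U"), ("U", "G")}

_NEG = np.int64(-(10 ** 9))

GAP_OPEN = 2
GAP_EXTEND = 1

CANONICAL = "canonical"
NON_CANONICAL = "non_canonical"
OTHER = "other"

SEED_WINDOWS = ((2, 7), (3, 8))


class DuplexError(ValueError):
    pass


class NegativeGenerationError(RuntimeError):
    """Raised when no acceptable shuffled miRNA is found within max_attempts."""


def _gap_cost(length: int) -> int:
    """Penalty of an unpaired run of `length` nucleotides between two pairs."""
    if length <= 0:
        return 0
    return GAP_OPEN + GAP_EXTEND * (length - 1)


def clean_rna(seq: str, what: str = "sequence") -> str:
    """Uppercase, convert T->U (with a warning), and validate the alphabet."""
    s = seq.upper().replace("T", "U") if "T" in seq.upper() else seq.upper()
    if "T" in seq.upper():
        warnings.warn(f"{what}: DNA alphabet detected, converting T->U")
    bad = sorted(set(s) - set(RNA_ALPHABET))
    if bad:
        raise DuplexError(f"{what}: invalid characters {bad!r}")
    if not s:
        raise DuplexError(f"{what}: empty sequence")
    return s


@dataclass(frozen=True)
class DuplexStructure:
    """A non-crossing intermolecular pairing between a miRNA and a site.

    ``pairs`` are 1-based ``(mirna_pos, site_pos)`` tuples, sorted by
    miRNA position; the duplex is antiparallel, so site positions strictly
    decrease along the list.
    """

    pairs: Tuple[Tuple[int, int], ...]
    pair_types: Tuple[str, ...]
    score: int
    mirna_len: int
    site_len: int

    def __post_init__(self) -> None:
        last: Optional[Tuple[int, int]] = None
        for (i, j), t in zip(self.pairs, self.pair_types):
            if not (1 <= i <= self.mirna_len and 1 <= j <= self.site_len):
                raise DuplexError(f"pair ({i},{j}) out of range")
            if t not in ("WC", "GU"):
                raise DuplexError(f"unknown pair type {t!r}")
            if last is not None and not (i > last[0] and j < last[1]):
                raise DuplexError(
                    f"pairs must be strictly monotone/antiparallel; "
                    f"({i},{j}) after {last}"
                )
            last = (i, j)

    def pair_at(self, mirna_pos: int) -> Optional[Tuple[int, str]]:
        """(site_pos, pair_type) of the pair at a miRNA position, if any."""
        for (i, j), t in zip(self.pairs, self.pair_types):
            if i == mirna_pos:
                return j, t
        return None

    @property
    def n_paired(self) -> int:
        return len(self.pairs)


def _pair_type(a: str, b: str) -> Optional[str]:
    if (a, b) in _WC_PAIRS:
        return "WC"
    if (a, b) in _GU_PAIRS:
        return "GU"
    return None


def predict_duplex(mirna: str, site: str) -> DuplexStructure:
    """Maximum-score non-crossing duplex between a miRNA and a target site.

    Among co-optimal structures the lexicographically smallest pair set
    (pairs compared as sorted ``(mirna_pos, site_pos)`` tuples) is
    returned, via a suffix DP followed by greedy front-to-back
    reconstruction.
    """
    a = clean_rna(mirna, "miRNA")
    b = clean_rna(site, "site")
    n, m = len(a), len(b)
    ai = np.array([_BASE_INDEX[c] for c in a])
    # reversed site: index j in `rev` is original site position m - j (1-based)
    rev = np.array([_BASE_INDEX[c] for c in b[::-1]])
    P = _PAIR_SCORE[ai[:, None], rev[None, :]]  # (n, m)

    gap = np.array([_gap_cost(d) for d in range(max(n, m))], dtype=np.int64)

    # suffix DP: f[i,j] = best score of a matching whose FIRST pair is (i,j)
    f = np.full((n, m), _NEG, dtype=np.int64)
    for i in range(n - 1, -1, -1):
        for j in range(m - 1, -1, -1):
            if P[i, j] == 0:
                continue
            best_cont = np.int64(0)
            sub = f[i + 1:, j + 1:]
            if sub.size:
                cand = (
                    sub
                    - gap[: sub.shape[0], None]
                    - gap[None, : sub.shape[1]]
                )
                best_cont = max(best_cont, cand.max())
            f[i, j] = P[i, j] + best_cont

    opt = int(max(0, f.max())) if f.size else 0
    pairs: List[Tuple[int, int]] = []
    types: List[str] = []
    if opt > 0:
        # greedy lexicographic reconstruction: at each step pick the
        # smallest admissible (mirna_pos, site_pos); site_pos = m - j, so
        # for equal i prefer the LARGEST reversed index j.
        prev: Optional[Tuple[int, int]] = None
        required = opt
        while required > 0:
            best_pick: Optional[Tuple[int, int]] = None
            if prev is None:
                cands = np.argwhere(f == required)
            else:
                pi, pj = prev
                cands = []
                for i in range(pi + 1, n):
                    for j in range(pj + 1, m):
                        if f[i, j] == _NEG:
                            continue
                        if f[i, j] - _gap_cost(i - pi - 1) - _gap_cost(
                            j - pj - 1
                        ) == required:
                            cands.append((i, j))
                cands = np.array(cands) if cands else np.empty((0, 2), int)
            if len(cands) == 0:  # pragma: no cover - DP guarantees progress
                raise AssertionError("duplex reconstruction failed")
            # order: i ascending, then site_pos ascending (= j descending)
            order = np.lexsort((-cands[:, 1], cands[:, 0]))
            best_pick = tuple(int(v) for v in cands[order[0]])
            i, j = best_pick
            site_pos = m - j
            t = _pair_type(a[i], b[::-1][j])
            assert t is not None
            pairs.append((i + 1, site_pos))
            types.append(t)
            required = int(f[i, j] - P[i, j])
            prev = (i, j)
    return DuplexStructure(
        pairs=tuple(pairs),
        pair_types=tuple(types),
        score=opt,
        mirna_len=n,
        site_len=m,
    )


# --------------------------------------------------------------------------
# batched window scoring (score only) for negative-site selection
# --------------------------------------------------------------------------

def window_scores(mirna: str, utr: str, window_len: int) -> np.ndarray:
    """Duplex score of the miRNA against every sliding window of the UTR.

    Three-state affine DP (pairs / unpaired-miRNA run / unpaired-site run)
    vectorised across windows; identical in value to
    :func:`predict_duplex` on each window.
    """
    a = clean_rna(mirna, "miRNA")
    u = clean_rna(utr, "UTR")
    n, L = len(a), window_len
    if L > len(u):
        raise DuplexError(
            f"window length {L} exceeds UTR length {len(u)}"
        )
    ui = np.array([_BASE_INDEX[c] for c in u])
    wins = np.lib.stride_tricks.sliding_window_view(ui, L)[:, ::-1]  # reversed
    B = wins.shape[0]
    ai = np.array([_BASE_INDEX[c] for c in a])
    P = _PAIR_SCORE[ai[None, :, None], wins[:, None, :]]  # (B, n, L)

    M = np.full((B, n + 1, L + 1), _NEG, dtype=np.int64)
    Ix = np.full_like(M, _NEG)
    Iy = np.full_like(M, _NEG)
    for i in range(1, n + 1):
        for j in range(1, L + 1):
            diag = np.maximum(
                0,
                np.maximum(
                    M[:, i - 1, j - 1],
                    np.maximum(Ix[:, i - 1, j - 1], Iy[:, i - 1, j - 1]),
                ),
            )
            p = P[:, i - 1, j - 1]
            M[:, i, j] = np.where(p > 0, p + diag, _NEG)
            Ix[:, i, j] = np.maximum(
                M[:, i - 1, j] - GAP_OPEN,
                np.maximum(
                    Ix[:, i - 1, j] - GAP_EXTEND,
                    Iy[:, i - 1, j] - GAP_OPEN,
                ),
            )
            Iy[:, i, j] = np.maximum(
                M[:, i, j - 1] - GAP_OPEN,
                np.maximum(
                    Iy[:, i, j - 1] - GAP_EXTEND,
                    Ix[:, i, j - 1] - GAP_OPEN,
                ),
            )
    best = M.reshape(B, -1).max(axis=1)
    return np.maximum(best, 0)


def best_window(mirna: str, utr: str, window_len: Optional[int] = None
                ) -> Tuple[int, str, int]:
    """Most favourable site window in a UTR: (offset, site_seq, score).

    Window length defaults to miRNA length + 5; ties go to the leftmost
    window.
    """
    if window_len is None:
        window_len = len(mirna) + 5
    scores = window_scores(mirna, utr, window_len)
    off = int(np.argmax(scores))  # argmax returns first = leftmost on ties
    return off, clean_rna(utr)[off:off + window_len], int(scores[off])


# --------------------------------------------------------------------------
# seed classification
# --------------------------------------------------------------------------

def window_status(duplex: DuplexStructure, lo: int, hi: int) -> str:
    """Classify one seed window (miRNA positions lo..hi, inclusive)."""
    inside = [
        ((i, j), t)
        for (i, j), t in zip(duplex.pairs, duplex.pair_types)
        if lo <= i <= hi
    ]
    size = hi - lo + 1
    if not inside:
        return OTHER
    # canonical: every window position WC-paired to consecutive site bases
    if (
        len(inside) == size
        and all(t == "WC" for _, t in inside)
        and all(
            inside[k + 1][0][1] == inside[k][0][1] - 1
            for k in range(len(inside) - 1)
        )
    ):
        return CANONICAL
    # non-canonical: GU allowed, at most one bulged/mismatched/unpaired
    # nucleotide in the window.  Between consecutive paired positions an
    # unpaired miRNA base facing a skipped site base is a single mismatch,
    # so defects between neighbours count as max(miRNA gap, site gap).
    defects = (inside[0][0][0] - lo) + (hi - inside[-1][0][0])
    for k in range(len(inside) - 1):
        (i1, j1), _ = inside[k]
        (i2, j2), _ = inside[k + 1]
        defects += max(i2 - i1 - 1, j1 - j2 - 1)
    if defects <= 1:
        return NON_CANONICAL
    return OTHER


def classify_seed(duplex: DuplexStructure) -> str:
    """Seed type of a duplex, decided from miRNA positions 2-8 only.

    The two windows (2-7, 3-8) are checked independently and the more
    favourable verdict wins: canonical > non_canonical > other.
    """
    statuses = [window_status(duplex, lo, hi) for lo, hi in SEED_WINDOWS]
    if CANONICAL in statuses:
        return CANONICAL
    if NON_CANONICAL in statuses:
        return NON_CANONICAL
    return OTHER


# --------------------------------------------------------------------------
# negative generation
# --------------------------------------------------------------------------

def seed_kmers(mirna: str) -> Tuple[str, str]:
    """The 6-mers at positions 2-7 and 3-8 (1-based, 5'->3')."""
    s = clean_rna(mirna)
    if len(s) < 8:
        raise DuplexError(f"miRNA too short for seed windows: {len(s)} nt")
    return s[1:7], s[2:8]


def generate_negative(
    positive: InteractionRecord,
    mirna_catalog: Iterable[str],
    utr: str,
    rng: np.random.Generator,
    max_attempts: int = 1000,
) -> InteractionRecord:
    """Synthesize a negative interaction from a positive one.

    The positive's miRNA is shuffled (uniform permutation) until its
    seed-region 6-mers at positions 2-7 and 3-8 match the corresponding
    6-mers of no catalog miRNA (exact, same-window string equality); the
    negative's site is the most favourable window of the given 3'UTR.
    """
    catalog = [clean_rna(s) for s in mirna_catalog]
    if not catalog:
        raise ValueError("miRNA catalog is empty")
    mirna = clean_rna(positive.mirna_seq)
    window_len = len(mirna) + 5
    if len(clean_rna(utr)) < window_len:
        raise DuplexError(
            f"UTR shorter than a site window ({window_len} nt) for "
            f"record {positive.interaction_id}"
        )
    forbidden_27 = {s[1:7] for s in catalog}
    forbidden_38 = {s[2:8] for s in catalog}

    shuffled = None
    letters = list(mirna)
    for _ in range(max_attempts):
        perm = "".join(rng.permutation(letters))
        k27, k38 = perm[1:7], perm[2:8]
        if k27 not in forbidden_27 and k38 not in forbidden_38:
            shuffled = perm
            break
    if shuffled is None:
        raise NegativeGenerationError(
            f"no valid shuffle for miRNA {positive.mirna_id!r} "
            f"after {max_attempts} attempts"
        )

    offset, site, _ = best_window(shuffled, utr, window_len)
    return InteractionRecord(
        interaction_id=f"{positive.interaction_id}_neg",
        mirna_id=f"{positive.mirna_id}_shuf",
        mirna_seq=shuffled,
        site_seq=site,
        label=0,
        species=positive.species,
        source=positive.source,
        utr_id=positive.utr_id,
        utr_length=len(utr),
        site_offset=offset,
    )
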