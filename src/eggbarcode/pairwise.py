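"""Pairwise alignment, percent identity, K2P distance, and library search.

The aligner is semi-global with affine gaps (Gotoh): end gaps on the *query*
row are free, so a barcode fragment floats inside a longer reference without
penalty, while internal indels are charged. A gap run of length L costs
``gap_open + (L - 1) * gap_extend``.

Percent identity uses compared columns only as its denominator: columns with
a gap, or with an IUPAC-ambiguous base in either row, are excluded. This
makes a "99%" criterion independent of fragment length and of ambiguity
calls, which is the convention barcode databases follow.

Transitions are A<->G and C<->T; every other substitution is a transversion.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .errors import InputError, SaturatedDistanceError, UndefinedIdentityError
from .records import BarcodeRecord, ReferenceLibrary

_NEG = np.float32(-1e30)

# nucleotide encoding: A,C,G,T -> 0..3 (transitions flip bit 1, i.e. x ^ 2);
# IUPAC ambiguity codes -> 4; anything else -> 5 (rejected on encode)
_CODE = np.full(256, 5, np.uint8)
for _i, _c in enumerate("ACGT"):
    _CODE[ord(_c)] = _i
    _CODE[ord(_c.lower())] = _i
for _c in "RYSWKMBDHVN":
    _CODE[ord(_c)] = 4
    _CODE[ord(_c.lower())] = 4
_CODE[ord("-")] = 6

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN-acgtryswkmbdhvn",
    "TGCAYRSWMKVHDBN-tgcayrswmkvhdbn",
)


def encode_sequence(seq: str) -> np.ndarray:
    arr = _CODE[np.frombuffer(seq.encode("ascii"), np.uint8)]
    if (arr >= 5).any():
        bad = seq[int(np.argmax(arr >= 5))]
        raise InputError(f"non-IUPAC character in sequence: {bad!r}")
    return arr


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@njit(cache=True, fastmath=True)
def _gotoh(a, b, match, mismatch, gap_open, gap_ext):  # pragma: no cover - numba
    """Affine-gap DP. ``a`` is the reference row; gaps in the query row
    (deletions, consuming reference bases) are free at both ends."""
    m, n = a.shape[0], b.shape[0]
    M = np.full((m + 1, n + 1), _NEG, np.float32)
    X = np.full((m + 1, n + 1), _NEG, np.float32)  # ends with gap in query
    Y = np.full((m + 1, n + 1), _NEG, np.float32)  # ends with gap in reference
    M[0, 0] = 0.0
    for i in range(1, m + 1):
        X[i, 0] = 0.0  # free leading reference overhang
    for j in range(1, n + 1):
        Y[0, j] = gap_open + (j - 1) * gap_ext
    for i in range(1, m + 1):
        ai = a[i - 1]
        for j in range(1, n + 1):
            bj = b[j - 1]
            s = match if (ai == bj and ai < 4 and bj < 4) else mismatch
            best_prev = M[i - 1, j - 1]
            if X[i - 1, j - 1] > best_prev:
                best_prev = X[i - 1, j - 1]
            if Y[i - 1, j - 1] > best_prev:
                best_prev = Y[i - 1, j - 1]
            M[i, j] = best_prev + s
            xo = M[i - 1, j] + gap_open
            if Y[i - 1, j] + gap_open > xo:
                xo = Y[i - 1, j] + gap_open
            xe = X[i - 1, j] + gap_ext
            X[i, j] = xo if xo > xe else xe
            yo = M[i, j - 1] + gap_open
            if X[i, j - 1] + gap_open > yo:
                yo = X[i, j - 1] + gap_open
            ye = Y[i, j - 1] + gap_ext
            Y[i, j] = yo if yo > ye else ye
    best = _NEG
    bi = m
    bs = 0
    for i in range(m + 1):  # free trailing reference overhang
        if M[i, n] > best:
            best = M[i, n]; bi = i; bs = 0
        if X[i, n] > best:
            best = X[i, n]; bi = i; bs = 1
        if Y[i, n] > best:
            best = Y[i, n]; bi = i; bs = 2
    return M, X, Y, best, bi, bs


@njit(cache=True, fastmath=True)
def _traceback(a, b, M, X, Y, bi, bs, match, mismatch, gap_open, gap_ext):  # pragma: no cover - numba
    m, n = a.shape[0], b.shape[0]
    ops = np.empty(m + n, np.int8)  # 0 diag, 1 gap-in-query, 2 gap-in-ref
    k = 0
    for _ in range(m - bi):
        ops[k] = 1; k += 1
    i, j, s = bi, n, bs
    tol = 1e-3
    while i > 0 or j > 0:
        if s == 0:
            ai = a[i - 1]; bj = b[j - 1]
            sc = match if (ai == bj and ai < 4 and bj < 4) else mismatch
            prev = M[i, j] - sc
            ops[k] = 0; k += 1
            i -= 1; j -= 1
            if abs(M[i, j] - prev) < tol:
                s = 0
            elif abs(X[i, j] - prev) < tol:
                s = 1
            else:
                s = 2
        elif s == 1:
            ops[k] = 1; k += 1
            cur = X[i, j]
            i -= 1
            if j == 0:
                s = 1  # inside the free leading-overhang zone
                continue
            if abs(X[i, j] + gap_ext - cur) < tol:
                s = 1
            elif abs(M[i, j] + gap_open - cur) < tol:
                s = 0
            else:
                s = 2
        else:
            ops[k] = 2; k += 1
            cur = Y[i, j]
            j -= 1
            if abs(Y[i, j] + gap_ext - cur) < tol:
                s = 2
            elif abs(M[i, j] + gap_open - cur) < tol:
                s = 0
            else:
                s = 1
        if i == 0 and j == 0:
            break
    while i > 0:
        ops[k] = 1; k += 1; i -= 1
    while j > 0:
        ops[k] = 2; k += 1; j -= 1
    return ops[:k][::-1]


@dataclass
class PairwiseAlignment:
    """A gapped pairwise alignment with substitution-class column counts.

    ``n_compared`` counts columns with an unambiguous base (A/C/G/T) in both
    rows; those columns partition into matches, transitions and transversions.
    """

    aligned_a: str
    aligned_b: str
    score: float
    n_columns: int
    n_compared: int
    n_matches: int
    n_transitions: int
    n_transversions: int

    def __post_init__(self):
        if len(self.aligned_a) != len(self.aligned_b) or len(self.aligned_a) != self.n_columns:
            raise InputError("aligned rows must have equal length n_columns")
        if self.n_matches + self.n_transitions + self.n_transversions != self.n_compared:
            raise InputError("column counts must partition n_compared")


def count_columns(aligned_a: str, aligned_b: str) -> tuple[int, int, int, int]:
    """(n_compared, n_matches, n_transitions, n_transversions) over columns
    where both rows carry an unambiguous base."""
    ea = _CODE[np.frombuffer(aligned_a.encode("ascii"), np.uint8)]
    eb = _CODE[np.frombuffer(aligned_b.encode("ascii"), np.uint8)]
    valid = (ea < 4) & (eb < 4)
    same = valid & (ea == eb)
    diff = valid & (ea != eb)
    ts = diff & ((ea ^ eb) == 2)  # A<->G, C<->T flip bit 1 of the encoding
    n_compared = int(valid.sum())
    n_matches = int(same.sum())
    n_ts = int(ts.sum())
    n_tv = int(diff.sum()) - n_ts
    return n_compared, n_matches, n_ts, n_tv


def align_pair(
    a: str,
    b: str,
    *,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
) -> PairwiseAlignment:
    """Optimal semi-global alignment of query ``b`` against reference ``a``.

    End gaps on the query row are free. Among co-optimal alignments the
    traceback prefers substitutions over gaps and ends at the smallest
    reference coordinate, so results are deterministic.
    """
    if not a or not b:
        raise InputError("cannot align an empty sequence")
    ea, eb = encode_sequence(a), encode_sequence(b)
    args = (np.float32(match), np.float32(mismatch),
            np.float32(gap_open), np.float32(gap_extend))
    M, X, Y, score, bi, bs = _gotoh(ea, eb, *args)
    ops = _traceback(ea, eb, M, X, Y, bi, bs, *args)
    ra = []
    rb = []
    i = j = 0
    for op in ops:
        if op == 0:
            ra.append(a[i]); rb.append(b[j]); i += 1; j += 1
        elif op == 1:
            ra.append(a[i]); rb.append("-"); i += 1
        else:
            ra.append("-"); rb.append(b[j]); j += 1
    aligned_a, aligned_b = "".join(ra), "".join(rb)
    n_compared, n_matches, n_ts, n_tv = count_columns(aligned_a, aligned_b)
    return PairwiseAlignment(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(score),
        n_columns=len(aligned_a),
        n_compared=n_compared,
        n_matches=n_matches,
        n_transitions=n_ts,
        n_transversions=n_tv,
    )


def percent_identity(aln: PairwiseAlignment) -> float:
    """Fraction of compared columns that match (gap/ambiguous columns are
    excluded from the denominator)."""
    if aln.n_compared < 1:
        raise UndefinedIdentityError(
            "no comparable columns: identity is undefined"
        )
    return aln.n_matches / aln.n_compared


def k2p_from_proportions(P: float, Q: float) -> float:
    """Kimura two-parameter distance from transition proportion P and
    transversion proportion Q:  d = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)].
    """
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturatedDistanceError(
            f"K2P distance undefined for P={P:.4f}, Q={Q:.4f} (saturation)"
        )
    return -0.5 * float(np.log(w1 * np.sqrt(w2)))


def k2p_distance(aln: PairwiseAlignment) -> float:
    """K2P distance of an alignment (substitutions per site)."""
    if aln.n_compared < 1:
        raise UndefinedIdentityError("no comparable columns: distance undefined")
    P = aln.n_transitions / aln.n_compared
    Q = aln.n_transversions / aln.n_compared
    return k2p_from_proportions(P, Q)


@dataclass
class Hit:
    reference_id: str
    family: str
    genus: str
    species: str
    identity: float
    rank: int


@dataclass
class HitList:
    """Ranked identity hits of one query against the whole library.

    ``best_species_identity`` / ``second_best_species_identity`` follow the
    interspecific-match convention of barcode databases: the best identity of
    the top species versus the best identity of the best *other* species,
    computed over the full library before any top-n truncation.
    ``second_best_species_identity`` is None when the library holds a single
    species.
    """

    query_id: str
    hits: list[Hit]
    best_species_identity: float
    second_best_species_identity: float | None


def _identities_against(query_seq: str, library: ReferenceLibrary,
                        **scoring) -> np.ndarray:
    out = np.empty(len(library))
    for k, ref in enumerate(library):
        aln = align_pair(ref.sequence, query_seq, **scoring)
        try:
            out[k] = percent_identity(aln)
        except UndefinedIdentityError:
            out[k] = 0.0
    return out


def orient_query(query: str, library: ReferenceLibrary, **scoring) -> str:
    """Return ``query`` or its reverse complement, whichever attains the
    higher best-hit identity against the library (tie: forward)."""
    fwd = _identities_against(query, library, **scoring)
    rc_seq = reverse_complement(query)
    rc = _identities_against(rc_seq, library, **scoring)
    return rc_seq if rc.max() > fwd.max() else query


def search_library(
    query: BarcodeRecord | str,
    library: ReferenceLibrary,
    top_n: int = 100,
    **scoring,
) -> HitList:
    """Exhaustively rank the library against a query by percent identity.

    The query is oriented first (forward vs reverse complement). Ties in
    identity break by reference id, so rankings are deterministic.
    """
    if top_n < 1:
        raise InputError("top_n must be >= 1")
    if isinstance(query, BarcodeRecord):
        qid, qseq = query.id, query.sequence
    else:
        qid, qseq = "query", query
    fwd = _identities_against(qseq, library, **scoring)
    rc_seq = reverse_complement(qseq)
    rc = _identities_against(rc_seq, library, **scoring)
    idents = rc if rc.max() > fwd.max() else fwd

    order = sorted(
        range(len(library)),
        key=lambda k: (-idents[k], library.records[k].id),
    )
    hits = []
    for rank, k in enumerate(order[:top_n], start=1):
        r = library.records[k]
        hits.append(Hit(r.id, r.family, r.genus, r.species,
                        float(idents[k]), rank))
    best_species = library.records[order[0]].species
    best_ident = float(idents[order[0]])
    second = None
    for k in order[1:]:
        if library.records[k].species != best_species:
            second = float(idents[k])
            break
    return HitList(
        query_id=qid,
        hits=hits,
        best_species_identity=best_ident,
        second_best_species_identity=second,
    )
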