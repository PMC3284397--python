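"""N-mer extraction, profile construction, and maximum-likelihood read
classification.

The classifier is a naive Bayes model over fixed-length N-mers: a read is
assigned to the training taxon maximising

    log Pr(read | taxon) = sum over windows w of log Pr(w | taxon)

with a uniform prior over taxa and the evidence term dropped (every taxon
is scored against the same read, so the denominator cancels in the
argmax). Per-taxon N-mer probabilities are relative frequencies with an
optional additive pseudocount ``alpha`` confined to that taxon's own
profile; there is no corpus-wide or genus-level prior. With ``alpha = 0``
an unseen N-mer scores negative infinity, so a read containing any N-mer
absent from every profile becomes unclassified.

Because no query-length or genome-length normalisation is applied, longer
training genomes enjoy a systematic advantage for queries that resemble no
taxon in the database; this length bias is inherent to the model and is
deliberately reproduced (see the package methods note).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import numpy as np

from ._seqcodes import (
    _COMPLEMENT,
    decode_kmer,
    encode_kmer,
    window_codes,
)

__all__ = [
    "KmerProfile",
    "ClassificationResult",
    "ReadScore",
    "extract_kmers",
    "reverse_complement",
    "build_profile",
    "kmer_log_probability",
    "score_read",
    "classify_read",
    "classify_reads",
    "EmptyProfileError",
]

#: Largest 4**n for which a profile is expanded into a dense log-probability
#: vector when scoring many reads (n <= 10). Above this the sparse path is used.
DENSE_LIMIT = 4**10


class EmptyProfileError(ValueError):
    """No training sequence was long enough to yield a single N-mer."""


@dataclass
class KmerProfile:
    """Sparse N-mer count table for one taxon.

    Attributes
    ----------
    taxon_id : str
        Opaque taxon label (strain or species depending on grouping policy).
    n : int
        N-mer length in bases.
    counts : dict
        Observed N-mer -> count; only N-mers seen in training are stored.
    total : int
        Sum of all counts.
    source_bp : int
        Total training-sequence length in bases (both strands counted when
        the profile was built with ``strand_policy="both"``).
    """

    taxon_id: str
    n: int
    counts: dict = field(default_factory=dict)
    total: int = 0
    source_bp: int = 0


class ReadScore(NamedTuple):
    """Log-likelihood of a read under one profile; ``log_likelihood`` is
    None when the read yields no scoreable N-mer."""

    log_likelihood: Optional[float]
    n_kmers: int


@dataclass
class ClassificationResult:
    """Outcome of maximum-likelihood classification of one read.

    ``best_taxon`` is None for unclassifiable reads (no scoreable N-mer, or
    every profile scored -inf under alpha=0). ``margin`` is
    ``best_score - runner_up_score`` in nats, ``inf`` for a single-taxon
    database.
    """

    read_id: str
    best_taxon: Optional[str]
    best_score: Optional[float]
    runner_up_taxon: Optional[str]
    margin: Optional[float]
    n_scored_kmers: int

    @property
    def classified(self) -> bool:
        return self.best_taxon is not None


def extract_kmers(sequence: str, n: int) -> list[str]:
    """All length-``n`` windows of ``sequence`` in order.

    Windows containing a character outside {A,C,G,T} (e.g. IUPAC ambiguity
    codes) are skipped; no fractional counting is attempted.
    """
    if n < 1:
        raise ValueError(f"n must be a positive integer, got {n}")
    codes = window_codes(sequence.upper(), n)
    return [decode_kmer(int(c), n) for c in codes]


def reverse_complement(sequence: str) -> str:
    """Watson-Crick reverse complement; N maps to N."""
    seq = sequence.upper()
    for ch in seq:
        if ch not in "ACGTN":
            raise ValueError(f"invalid character {ch!r} for reverse complement")
    return seq.translate(_COMPLEMENT)[::-1]


def build_profile(
    taxon_id: str,
    sequences: Iterable[str],
    n: int,
    strand_policy: str = "given",
) -> KmerProfile:
    """Aggregate N-mer counts over all training sequences of one taxon.

    ``strand_policy="both"`` additionally counts each sequence's reverse
    complement, doubling ``source_bp``.
    """
    if n < 1:
        raise ValueError(f"n must be a positive integer, got {n}")
    if strand_policy not in ("given", "both"):
        raise ValueError(f"unknown strand_policy {strand_policy!r}")
    code_counts: dict[int, int] = {}
    source_bp = 0
    any_long_enough = False
    for seq in sequences:
        seq = seq.upper()
        strands = [seq]
        if strand_policy == "both":
            strands.append(reverse_complement(seq))
        for s in strands:
            source_bp += len(s)
            if len(s) >= n:
                any_long_enough = True
            codes = window_codes(s, n)
            if codes.size:
                uniq, cts = np.unique(codes, return_counts=True)
                for c, k in zip(uniq.tolist(), cts.tolist()):
                    code_counts[c] = code_counts.get(c, 0) + k
    if not any_long_enough:
        raise EmptyProfileError(
            f"taxon {taxon_id!r}: no training sequence of length >= {n}"
        )
    counts = {decode_kmer(c, n): k for c, k in sorted(code_counts.items())}
    return KmerProfile(
        taxon_id=taxon_id,
        n=n,
        counts=counts,
        total=sum(counts.values()),
        source_bp=source_bp,
    )


def kmer_log_probability(profile: KmerProfile, kmer: str, alpha: float = 1.0) -> float:
    """log[(count + alpha) / (total + alpha * 4**n)] in nats.

    With ``alpha = 0`` an unseen N-mer returns ``-inf`` (the strict
    no-smoothing behaviour).
    """
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha}")
    if len(kmer) != profile.n:
        raise ValueError(
            f"k-mer {kmer!r} has length {len(kmer)}, profile expects {profile.n}"
        )
    encode_kmer(kmer)  # alphabet check
    num = profile.counts.get(kmer, 0) + alpha
    if num == 0:
        return -math.inf
    return math.log(num) - math.log(profile.total + alpha * 4**profile.n)


class _ProfileScorer:
    """Precomputed per-N-mer log-probabilities for fast repeated scoring."""

    def __init__(self, profile: KmerProfile, alpha: float):
        if alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {alpha}")
        n = profile.n
        denom = math.log(profile.total + alpha * 4**n)
        self._base = math.log(alpha) - denom if alpha > 0 else -math.inf
        self._dense: Optional[np.ndarray] = None
        self._sparse: Optional[dict[int, float]] = None
        if 4**n <= DENSE_LIMIT:
            arr = np.full(4**n, self._base)
            for kmer, count in profile.counts.items():
                arr[encode_kmer(kmer)] = math.log(count + alpha) - denom
            self._dense = arr
        else:
            self._sparse = {
                encode_kmer(k): math.log(c + alpha) - denom
                for k, c in profile.counts.items()
            }

    def score(self, codes: np.ndarray) -> float:
        if self._dense is not None:
            return float(self._dense[codes].sum())
        sparse, base = self._sparse, self._base
        return sum(sparse.get(int(c), base) for c in codes)


def score_read(
    read: str,
    profile: KmerProfile,
    alpha: float = 1.0,
    strand_policy: str = "forward",
) -> ReadScore:
    """Sum of N-mer log-probabilities over the read's valid windows.

    Under ``strand_policy="max_of_strands"`` the larger of the forward and
    reverse-complement scores is returned (same window count by symmetry).
    Returns ``ReadScore(None, 0)`` when no window is scoreable.
    """
    if strand_policy not in ("forward", "max_of_strands"):
        raise ValueError(f"unknown strand_policy {strand_policy!r}")
    read = read.upper()
    codes = window_codes(read, profile.n)
    if codes.size == 0:
        return ReadScore(None, 0)
    scorer = _ProfileScorer(profile, alpha)
    score = scorer.score(codes)
    if strand_policy == "max_of_strands":
        rc_codes = window_codes(_loose_revcomp(read), profile.n)
        score = max(score, scorer.score(rc_codes))
    return ReadScore(score, int(codes.size))


def _loose_revcomp(seq: str) -> str:
    """Reverse complement that passes unknown characters through unchanged
    (they are skipped at windowing anyway)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _database_scorers(database, alpha: float) -> dict[str, _ProfileScorer]:
    """Per-taxon scorers, cached on the database object keyed by alpha."""
    cache = getattr(database, "_scorer_cache", None)
    if cache is None:
        cache = {}
        try:
            database._scorer_cache = cache
        except (AttributeError, TypeError):
            pass
    if alpha not in cache:
        cache[alpha] = {
            taxon: _ProfileScorer(profile, alpha)
            for taxon, profile in database.profiles.items()
        }
    return cache[alpha]


def classify_read(
    read: str,
    database,
    alpha: float = 1.0,
    strand_policy: str = "max_of_strands",
    read_id: str = "read",
) -> ClassificationResult:
    """Assign a read to the training taxon with maximal log-likelihood.

    Ties are broken by lexicographically smallest taxon_id so results are
    reproducible across runs and platforms. Reads with no scoreable N-mer,
    or scoring -inf against every taxon, come back unclassified.
    """
    if not database.profiles:
        raise ValueError("cannot classify against an empty database")
    if strand_policy not in ("forward", "max_of_strands"):
        raise ValueError(f"unknown strand_policy {strand_policy!r}")
    read = read.upper()
    n = database.n
    codes = window_codes(read, n)
    if codes.size == 0:
        return ClassificationResult(read_id, None, None, None, None, 0)
    rc_codes = (
        window_codes(_loose_revcomp(read), n)
        if strand_policy == "max_of_strands"
        else None
    )
    scorers = _database_scorers(database, alpha)
    best_taxon = runner_taxon = None
    best = runner = -math.inf
    for taxon in sorted(scorers):
        s = scorers[taxon].score(codes)
        if rc_codes is not None:
            s = max(s, scorers[taxon].score(rc_codes))
        if s > best:
            runner, runner_taxon = best, best_taxon
            best, best_taxon = s, taxon
        elif s > runner:
            runner, runner_taxon = s, taxon
    if best == -math.inf:
        return ClassificationResult(read_id, None, None, None, None, int(codes.size))
    if runner_taxon is None:
        margin: float = math.inf
    else:
        margin = best - runner
    return ClassificationResult(
        read_id=read_id,
        best_taxon=best_taxon,
        best_score=best,
        runner_up_taxon=runner_taxon,
        margin=margin,
        n_scored_kmers=int(codes.size),
    )


def classify_reads(
    reads: Iterable[tuple[str, str]],
    database,
    alpha: float = 1.0,
    strand_policy: str = "max_of_strands",
) -> list[ClassificationResult]:
    """Classify (read_id, sequence) pairs; see :func:`classify_read`."""
    return [
        classify_read(seq, database, alpha=alpha, strand_policy=strand_policy, read_id=rid)
        for rid, seq in reads
    ]
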