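"""Design of synthetic spike-in standards (sequins) from source genomes.

A sequin is derived from a real (or synthetic) microbial genome by cutting a
random 1-10 kb window, *inverting* it -- plain character-order reversal, not
reverse complementation -- and screening the result against every source
genome so that it retains the composition of its parent (length, GC,
homopolymer content) while losing primary-sequence alignability.  Reversal is
chosen over reverse complementation because it preserves per-base composition
exactly and the reversed sequence cannot simply be re-aligned to the opposite
strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenomeProfile",
    "CandidateWindow",
    "ScreenResult",
    "SequinRecord",
    "DesignConfig",
    "DesignReport",
    "profile_genome",
    "sample_candidates",
    "invert_sequence",
    "homology_screen",
    "design_sequins",
    "gc_content",
    "reverse_complement",
    "KmerIndex",
]

_BASES = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# 2-bit base codes used for integer k-mer encoding
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _validate_sequence(sequence: str) -> None:
    """Raise ValueError naming the first offending position for non-ACGT input."""
    if not sequence:
        raise ValueError("empty sequence")
    bad = set(sequence) - _BASES
    if bad:
        pos = next(i for i, c in enumerate(sequence) if c in bad)
        raise ValueError(
            f"non-ACGT symbol {sequence[pos]!r} at position {pos}"
        )


def gc_content(sequence: str) -> float:
    """Fraction of G+C bases."""
    _validate_sequence(sequence)
    return (sequence.count("G") + sequence.count("C")) / len(sequence)


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def invert_sequence(sequence: str) -> str:
    """Reverse the character order of *sequence* (no complementation).

    An involution that preserves length, per-base composition, GC content and
    the multiset of homopolymer run lengths.
    """
    _validate_sequence(sequence)
    return sequence[::-1]


def homopolymer_runs(sequence: str, min_len: int) -> list[tuple[int, int]]:
    """Maximal single-base runs of length >= min_len as 0-based half-open intervals."""
    runs: list[tuple[int, int]] = []
    i, n = 0, len(sequence)
    while i < n:
        j = i + 1
        while j < n and sequence[j] == sequence[i]:
            j += 1
        if j - i >= min_len:
            runs.append((i, j))
        i = j
    return runs


@dataclass(frozen=True)
class GenomeProfile:
    """Summary features of one source genome."""

    id: str
    length: int
    gc: float
    homopolymer_count: int
    taxon_label: str = ""
    environment_label: str = ""

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("length must be positive")
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError("gc must be a fraction in [0, 1]")


@dataclass(frozen=True)
class CandidateWindow:
    source_id: str
    start: int  # 0-based
    end: int  # exclusive
    sequence: str
    gc: float


@dataclass(frozen=True)
class ScreenResult:
    passed: bool
    longest_shared_match: int
    matched_background_id: str = ""


@dataclass(frozen=True)
class SequinRecord:
    """One synthetic standard: an inverted genome window."""

    id: str
    sequence: str
    length: int
    gc: float
    source_id: str
    source_window: tuple[int, int]


@dataclass
class DesignConfig:
    length_min: int = 1000
    length_max: int = 10000
    candidates_per_genome: int = 200
    kmer: int = 18
    min_match: int = 30
    min_homopolymer: int = 6
    gc_targets: dict[str, float] = field(default_factory=dict)


@dataclass
class DesignReport:
    sequins: list[SequinRecord]
    failures: dict[str, str]  # genome id -> reason


def profile_genome(sequence: str, min_homopolymer: int = 6, *, id: str = "",
                   taxon_label: str = "", environment_label: str = "") -> GenomeProfile:
    """Profile a genome sequence: length, GC fraction, homopolymer-run count."""
    _validate_sequence(sequence)
    return GenomeProfile(
        id=id,
        length=len(sequence),
        gc=gc_content(sequence),
        homopolymer_count=len(homopolymer_runs(sequence, min_homopolymer)),
        taxon_label=taxon_label,
        environment_label=environment_label,
    )


def sample_candidates(
    genome_id: str,
    sequence: str,
    length_range: tuple[int, int],
    n: int,
    rng_seed: int,
) -> list[CandidateWindow]:
    """Draw *n* random windows with lengths uniform in ``length_range``.

    Start offsets are uniform over the valid range for each drawn length, so a
    window never overruns the genome end.  Windows containing non-ACGT symbols
    (ambiguity codes) are discarded.
    """
    lo, hi = length_range
    if not 1 <= lo <= hi:
        raise ValueError("invalid length range")
    if len(sequence) < hi:
        raise ValueError(
            f"genome {genome_id!r} ({len(sequence)} bp) shorter than the "
            f"maximum window length {hi}"
        )
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng_seed)
    lengths = rng.integers(lo, hi + 1, size=n)
    out: list[CandidateWindow] = []
    for length in lengths:
        length = int(length)
        start = int(rng.integers(0, len(sequence) - length + 1))
        window = sequence[start : start + length]
        if set(window) - _BASES:
            continue  # ambiguity codes: drop the window
        out.append(
            CandidateWindow(
                source_id=genome_id,
                start=start,
                end=start + length,
                sequence=window,
                gc=gc_content(window),
            )
        )
    return out


def _encode(sequence: str) -> np.ndarray:
    arr = _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    if arr.max(initial=0) > 3:
        _validate_sequence(sequence)  # raises with position
    return arr.astype(np.int64)


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Integer codes of all overlapping k-mers of a 2-bit coded sequence."""
    if len(codes) < k:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return win @ powers


class KmerIndex:
    """Sorted k-mer index over a collection of background sequences.

    Both strands of every sequence are indexed so that a candidate matching
    the reverse complement of a background region is still caught.  With
    ``stride`` s > 1 only every s-th background k-mer is stored: any shared
    substring of length >= k + s - 1 still contains an indexed seed and is
    found (and, via maximal extension, measured) exactly, at 1/s the index
    size.  Queries always use every candidate k-mer.
    """

    def __init__(self, sequences: dict[str, str], k: int, stride: int = 1):
        if k < 8:
            raise ValueError("k-mer size < 8: seed too unspecific")
        if k > 31:
            raise ValueError("k-mer size > 31 not supported")
        if stride < 1:
            raise ValueError("stride must be >= 1")
        self.k = k
        self.stride = stride
        self.names: list[str] = []
        self.seqs: list[str] = []  # forward and RC interleaved
        kmers: list[np.ndarray] = []
        locs: list[np.ndarray] = []
        for name, seq in sequences.items():
            for strand, s in (("+", seq), ("-", reverse_complement(seq))):
                idx = len(self.seqs)
                self.names.append(name)
                self.seqs.append(s)
                km = _kmer_codes(_encode(s), k)[:: stride]
                kmers.append(km)
                loc = np.empty((len(km), 2), dtype=np.int64)
                loc[:, 0] = idx
                loc[:, 1] = np.arange(len(km)) * stride
                locs.append(loc)
        if kmers:
            allk = np.concatenate(kmers)
            allloc = np.concatenate(locs)
            order = np.argsort(allk, kind="stable")
            self._kmers = allk[order]
            self._locs = allloc[order]
        else:
            self._kmers = np.empty(0, dtype=np.int64)
            self._locs = np.empty((0, 2), dtype=np.int64)

    def add(self, name: str, seq: str) -> None:
        """Add one more background sequence (re-sorts the index)."""
        extra_k: list[np.ndarray] = [self._kmers]
        extra_l: list[np.ndarray] = [self._locs]
        for s in (seq, reverse_complement(seq)):
            idx = len(self.seqs)
            self.names.append(name)
            self.seqs.append(s)
            km = _kmer_codes(_encode(s), self.k)[:: self.stride]
            loc = np.empty((len(km), 2), dtype=np.int64)
            loc[:, 0] = idx
            loc[:, 1] = np.arange(len(km)) * self.stride
            extra_k.append(km)
            extra_l.append(loc)
        allk = np.concatenate(extra_k)
        allloc = np.concatenate(extra_l)
        order = np.argsort(allk, kind="stable")
        self._kmers = allk[order]
        self._locs = allloc[order]

    def longest_match(self, candidate: str) -> tuple[int, str]:
        """Longest exact substring shared with any indexed sequence.

        Exact for matches of length >= k; shorter shared substrings contain no
        seed and yield (0, "").
        """
        cand_kmers = _kmer_codes(_encode(candidate), self.k)
        if len(cand_kmers) == 0 or len(self._kmers) == 0:
            return 0, ""
        left = np.searchsorted(self._kmers, cand_kmers, side="left")
        safe = np.minimum(left, len(self._kmers) - 1)
        is_hit = self._kmers[safe] == cand_kmers
        best_len, best_name = 0, ""
        hit_positions = np.nonzero(is_hit)[0]
        for qpos in hit_positions:
            j0 = left[qpos]
            j1 = j0
            while j1 < len(self._kmers) and self._kmers[j1] == cand_kmers[qpos]:
                j1 += 1
            for j in range(j0, j1):
                sidx, tpos = int(self._locs[j, 0]), int(self._locs[j, 1])
                target = self.seqs[sidx]
                # maximal extension around the seed
                qi, ti = qpos - 1, tpos - 1
                while qi >= 0 and ti >= 0 and candidate[qi] == target[ti]:
                    qi -= 1
                    ti -= 1
                qj, tj = qpos + self.k, tpos + self.k
                while (
                    qj < len(candidate)
                    and tj < len(target)
                    and candidate[qj] == target[tj]
                ):
                    qj += 1
                    tj += 1
                length = qj - qi - 1
                if length > best_len:
                    best_len = length
                    best_name = self.names[sidx]
        return best_len, best_name


def homology_screen(
    candidate: str,
    background: dict[str, str] | KmerIndex,
    k: int = 18,
    min_match: int = 30,
) -> ScreenResult:
    """Screen a candidate against background sequences (both strands).

    The internal surrogate for a BLAST-vs-nt query: the candidate fails if it
    shares an exact substring of length >= ``min_match`` with any background
    sequence or its reverse complement.  Matches are found by k-mer seeding
    and maximal extension: every shared substring of length
    >= k + stride - 1 (<= min_match by construction) is found and measured
    exactly, so ``passed`` is always exact; shorter shared substrings may be
    reported as 0.
    """
    if k > min_match:
        raise ValueError("k must be <= min_match")
    if isinstance(background, KmerIndex):
        index = background
    else:
        index = KmerIndex(background, k, stride=max(1, min_match - k + 1))
    if index.k != k:
        raise ValueError("index k does not match requested k")
    if index.k + index.stride - 1 > min_match:
        raise ValueError("index stride too coarse for requested min_match")
    longest, name = index.longest_match(candidate)
    return ScreenResult(
        passed=longest < min_match,
        longest_shared_match=longest,
        matched_background_id=name if longest >= min_match else "",
    )


def design_sequins(
    genomes: dict[str, str],
    config: DesignConfig | None = None,
    rng_seed: int = 0,
) -> DesignReport:
    """Design one sequin per source genome.

    For each genome: sample candidate windows, invert each, screen the
    inverted candidates against every input genome (both strands) and against
    previously accepted sequins, then among passing candidates keep the one
    whose GC is closest to the source genome's GC (or a per-genome override
    from ``config.gc_targets``).  IDs are MG_01..MG_n in input order.  Genomes
    for which no candidate passes are reported as failures, not raised.
    """
    cfg = config or DesignConfig()
    if not genomes:
        raise ValueError("at least one genome required")
    index = KmerIndex(genomes, cfg.kmer,
                      stride=max(1, cfg.min_match - cfg.kmer + 1))
    rng = np.random.default_rng(rng_seed)
    sequins: list[SequinRecord] = []
    failures: dict[str, str] = {}
    width = max(2, len(str(len(genomes))))
    for gi, (gid, gseq) in enumerate(genomes.items()):
        target_gc = cfg.gc_targets.get(gid, gc_content(gseq))
        seed = int(rng.integers(0, 2**31))
        try:
            candidates = sample_candidates(
                gid, gseq, (cfg.length_min, cfg.length_max),
                cfg.candidates_per_genome, seed,
            )
        except ValueError as exc:
            failures[gid] = str(exc)
            continue
        best: CandidateWindow | None = None
        best_seq = ""
        best_dist = np.inf
        for cand in candidates:
            inverted = invert_sequence(cand.sequence)
            result = homology_screen(inverted, index, cfg.kmer, cfg.min_match)
            if not result.passed:
                continue
            dist = abs(cand.gc - target_gc)
            # tie-break deterministically by window coordinates
            if dist < best_dist or (
                dist == best_dist and best is not None
                and (cand.start, cand.end) < (best.start, best.end)
            ):
                best, best_seq, best_dist = cand, inverted, dist
        if best is None:
            failures[gid] = "no candidate passed the homology screen"
            continue
        record = SequinRecord(
            id=f"MG_{len(sequins) + 1:0{width}d}",
            sequence=best_seq,
            length=len(best_seq),
            gc=best.gc,
            source_id=gid,
            source_window=(best.start, best.end),
        )
        sequins.append(record)
        index.add(record.id, record.sequence)
    return DesignReport(sequins=sequins, failures=failures)
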