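"""Spiked-community composition and read simulation with ground truth.

The simulator replaces an external read simulator for desk-scale validation
of the spike-in workflow.  It draws fragments multinomially with
probability proportional to each reference's expected read *mass* (input
concentration x length for spike members), emits paired 2x125 bp short reads
or lognormal-length long reads, injects substitution and indel errors, and
always records a ground-truth placement plus an edit log for every read, so
downstream coverage and error-rate analyses can run alignment-free.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .design import homopolymer_runs, reverse_complement
from .mixtures import MixtureSpec

__all__ = [
    "CommunitySpec",
    "ErrorModel",
    "Placements",
    "ReadSet",
    "compose_sample",
    "simulate_short_reads",
    "simulate_long_reads",
    "generate_fixture_genomes",
    "apply_edits",
]

_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


@dataclass(frozen=True)
class ErrorModel:
    """Per-base error process applied to simulated reads.

    Rates are per sequenced base.  ``homopolymer_indel_rate``, when set,
    replaces the combined indel rate inside annotated homopolymer runs of
    length >= ``min_homopolymer`` (long-read mode only).  Defaults are
    error-free; see the short/long presets.
    """

    mismatch_rate: float = 0.0
    insertion_rate: float = 0.0
    deletion_rate: float = 0.0
    homopolymer_indel_rate: float = 0.0
    min_homopolymer: int = 6
    read_length: int = 125
    fragment_mean: float = 350.0
    fragment_sd: float = 50.0
    long_read_mean: float = 2590.0
    long_read_sigma: float = 0.55  # lognormal shape
    quality_char: str = "?"  # Phred 30

    def __post_init__(self) -> None:
        for r in (self.mismatch_rate, self.insertion_rate, self.deletion_rate,
                  self.homopolymer_indel_rate):
            if not 0.0 <= r < 1.0:
                raise ValueError("error rates must be in [0, 1)")
        if self.homopolymer_indel_rate and self.homopolymer_indel_rate < max(
            self.insertion_rate, self.deletion_rate
        ):
            raise ValueError(
                "homopolymer_indel_rate must be >= the baseline indel rates"
            )

    @classmethod
    def illumina(cls) -> "ErrorModel":
        """Short-read defaults: printed Illumina error-rate estimates."""
        return cls(mismatch_rate=0.00127, insertion_rate=0.0000385,
                   deletion_rate=0.0000385)

    @classmethod
    def nanopore(cls) -> "ErrorModel":
        """Long-read defaults: printed MinION error-rate estimates, with the
        elevated homopolymer indel rate."""
        return cls(mismatch_rate=0.0712, insertion_rate=0.04355,
                   deletion_rate=0.04355, homopolymer_indel_rate=0.167,
                   quality_char="+")  # Phred 10

    @classmethod
    def error_free(cls) -> "ErrorModel":
        return cls()


@dataclass
class CommunitySpec:
    """Resolved per-reference expected read-mass weights for one sample."""

    weights: dict[str, float]
    ref_lengths: dict[str, int]
    sequences: dict[str, str] = field(default_factory=dict)
    spike_ids: frozenset[str] = frozenset()
    mixture: MixtureSpec | None = None

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be non-negative")
        total = sum(self.weights.values())
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            raise ValueError(f"weights must sum to 1, got {total}")


def compose_sample(
    members: list[tuple[str, str | int, float]],
    mixture: MixtureSpec | None = None,
    spike_mode: tuple[str, float] | None = None,
    sequin_lengths: dict[str, int] | None = None,
    sequin_sequences: dict[str, str] | None = None,
) -> CommunitySpec:
    """Resolve read-mass weights for a community plus an optional spike.

    ``members`` are (ref_id, sequence-or-length, mass) tuples; ``mass`` is an
    arbitrary-unit DNA mass (only ratios matter in fractional mode, absolute
    values matter in fixed mode).  Spike members come from ``mixture`` with
    mass proportional to concentration x length.

    spike_mode ("fractional", f): spike mass is rescaled to a fraction f of
    the total sample mass -- what a lab does when spiking at, say, 1-5%
    fractional abundance.  spike_mode ("fixed", s): the spike contributes a
    constant mass s while community mass varies between samples, so the
    spike's read share falls as community load rises.
    """
    if not members and mixture is None:
        raise ValueError("members must not be empty without a spike mixture")
    lengths: dict[str, int] = {}
    sequences: dict[str, str] = {}
    comm_mass: dict[str, float] = {}
    for ref_id, seq_or_len, mass in members:
        if isinstance(seq_or_len, str):
            lengths[ref_id] = len(seq_or_len)
            sequences[ref_id] = seq_or_len
        else:
            lengths[ref_id] = int(seq_or_len)
        if mass < 0:
            raise ValueError("member mass must be non-negative")
        comm_mass[ref_id] = float(mass)

    spike_mass: dict[str, float] = {}
    spike_ids: frozenset[str] = frozenset()
    if mixture is not None:
        sequin_lengths = dict(sequin_lengths or {})
        for e in mixture.entries:
            length = e.length or sequin_lengths.get(e.sequin_id, 0)
            if length <= 0:
                raise ValueError(f"no length known for sequin {e.sequin_id}")
            lengths[e.sequin_id] = length
            spike_mass[e.sequin_id] = e.concentration * length
        spike_ids = frozenset(spike_mass)
        if sequin_sequences:
            sequences.update(sequin_sequences)

    total_comm = sum(comm_mass.values())
    total_spike = sum(spike_mass.values())
    if spike_mass and spike_mode is None:
        spike_mode = ("fractional", 0.01)
    if spike_mode is not None and spike_mass:
        mode, value = spike_mode
        if mode == "fractional":
            if not 0.0 < value < 1.0:
                raise ValueError("fractional spike f must be in (0, 1)")
            if total_comm == 0:
                # neat spike: the mixture is the whole sample
                weights = {r: m / total_spike for r, m in spike_mass.items()}
                return CommunitySpec(weights, lengths, sequences, spike_ids, mixture)
            weights = {r: (1 - value) * m / total_comm for r, m in comm_mass.items()}
            weights.update(
                {r: value * m / total_spike for r, m in spike_mass.items()}
            )
        elif mode == "fixed":
            if value <= 0:
                raise ValueError("fixed spike mass must be positive")
            scale = value / total_spike
            total = total_comm + value
            weights = {r: m / total for r, m in comm_mass.items()}
            weights.update({r: m * scale / total for r, m in spike_mass.items()})
        else:
            raise ValueError(f"unknown spike mode {mode!r}")
    else:
        total = total_comm + total_spike
        if total <= 0:
            raise ValueError("total sample mass must be positive")
        weights = {r: m / total for r, m in comm_mass.items()}
        weights.update({r: m / total for r, m in spike_mass.items()})
    return CommunitySpec(weights, lengths, sequences, spike_ids, mixture)


class Placements:
    """Column-oriented table of ground-truth read placements."""

    def __init__(
        self,
        ref_names: list[str],
        ref_idx: np.ndarray,
        start: np.ndarray,
        end: np.ndarray,
        strand: np.ndarray,  # +1 / -1
        read_ids: list[str] | None = None,
        edits: list[str] | None = None,
    ):
        self.ref_names = ref_names
        self.ref_idx = ref_idx
        self.start = start
        self.end = end
        self.strand = strand
        self._read_ids = read_ids
        self.edits = edits

    def __len__(self) -> int:
        return len(self.ref_idx)

    @property
    def read_ids(self) -> list[str]:
        if self._read_ids is None:
            self._read_ids = [f"read_{i}" for i in range(len(self))]
        return self._read_ids

    def injected_counts(self) -> tuple[int, int, int]:
        """Total (mismatch, insertion, deletion) counts over all reads."""
        if not self.edits:
            return (0, 0, 0)
        mm = ins = dele = 0
        for s in self.edits:
            if not s:
                continue
            for op in s.split(","):
                kind = op.split(":")[1]
                if kind == "X":
                    mm += 1
                elif kind == "I":
                    ins += 1
                else:
                    dele += 1
        return (mm, ins, dele)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            ids = self.read_ids
            edits = self.edits or [""] * len(self)
            for i in range(len(self)):
                fh.write(
                    f"{self.ref_names[self.ref_idx[i]]}\t{self.start[i]}\t"
                    f"{self.end[i]}\t{ids[i]}\t"
                    f"{'+' if self.strand[i] > 0 else '-'}\t{edits[i]}\n"
                )

    @classmethod
    def from_tsv(cls, path) -> "Placements":
        names: list[str] = []
        name_idx: dict[str, int] = {}
        refs, starts, ends, strands = [], [], [], []
        ids, edits = [], []
        with open(path) as fh:
            for line in fh:
                ref, s, e, rid, strand, edit = line.rstrip("\n").split("\t")
                if ref not in name_idx:
                    name_idx[ref] = len(names)
                    names.append(ref)
                refs.append(name_idx[ref])
                starts.append(int(s))
                ends.append(int(e))
                strands.append(1 if strand == "+" else -1)
                ids.append(rid)
                edits.append(edit)
        return cls(
            names,
            np.asarray(refs, dtype=np.int32),
            np.asarray(starts, dtype=np.int64),
            np.asarray(ends, dtype=np.int64),
            np.asarray(strands, dtype=np.int8),
            ids,
            edits,
        )


@dataclass
class ReadSet:
    """Simulated reads; ``reads`` is empty in placements-only mode."""

    reads: list[tuple[str, str, str]]  # (read_id, sequence, quality)
    placements: Placements

    def write_fastq(self, path) -> None:
        with open(path, "w") as fh:
            for rid, seq, qual in self.reads:
                fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def apply_edits(template: str, edits: str) -> str:
    """Reconstruct a read from its oriented reference template and edit log.

    Edit ops are ``pos:X:base`` (substitute), ``pos:I:base`` (insert *base*
    before template position pos) and ``pos:D:-`` (delete the base at pos),
    with positions in template coordinates, ascending.
    """
    if not edits:
        return template
    out: list[str] = []
    cursor = 0
    for op in edits.split(","):
        pos_s, kind, base = op.split(":")
        pos = int(pos_s)
        out.append(template[cursor:pos])
        if kind == "X":
            out.append(base)
            cursor = pos + 1
        elif kind == "I":
            out.append(base)
            cursor = pos
        elif kind == "D":
            cursor = pos + 1
        else:
            raise ValueError(f"unknown edit op {kind!r}")
    out.append(template[cursor:])
    return "".join(out)


def _draw_refs(
    spec: CommunitySpec, n: int, rng: np.random.Generator
) -> tuple[list[str], np.ndarray, np.ndarray]:
    names = sorted(spec.weights)
    w = np.array([spec.weights[r] for r in names])
    w = w / w.sum()
    lens = np.array([spec.ref_lengths[r] for r in names], dtype=np.int64)
    idx = rng.choice(len(names), size=n, p=w).astype(np.int32)
    return names, idx, lens


def _inject_errors_batch(
    templates: list[str],
    rates: tuple[float, float, float],
    rng: np.random.Generator,
) -> list[str]:
    """Draw edit logs for a batch of template strings (uniform rates)."""
    mm, ins, dele = rates
    p_any = mm + ins + dele
    out: list[str] = []
    if p_any == 0:
        return [""] * len(templates)
    for tpl in templates:
        n = len(tpl)
        u = rng.random(n)
        ops: list[str] = []
        hit = np.nonzero(u < p_any)[0]
        for pos in hit:
            x = u[pos]
            if x < mm:
                orig = tpl[pos]
                base = "ACGT"[(_CODE[ord(orig)] + 1 + int(rng.integers(3))) % 4]
                ops.append(f"{pos}:X:{base}")
            elif x < mm + ins:
                base = "ACGT"[int(rng.integers(4))]
                ops.append(f"{pos}:I:{base}")
            else:
                ops.append(f"{pos}:D:-")
        out.append(",".join(ops))
    return out


def simulate_short_reads(
    spec: CommunitySpec,
    n_pairs: int,
    model: ErrorModel | None = None,
    seed: int = 0,
    emit: str = "fastq",
) -> ReadSet:
    """Simulate paired-end short reads (default 2 x 125 bp).

    Fragments are drawn per reference with probability proportional to its
    resolved mass weight; read 1 comes from the fragment's 5' end on the
    forward strand and read 2 from the 3' end on the reverse strand.
    Placements (and injected-edit logs) are always produced; sequence/FASTQ
    assembly is skipped when ``emit == "placements_only"``.  Identical seeds
    give byte-identical output.
    """
    if n_pairs < 0:
        raise ValueError("n_pairs must be >= 0")
    model = model or ErrorModel.error_free()
    rl = model.read_length
    rng = np.random.default_rng(seed)
    names, idx, lens = _draw_refs(spec, n_pairs, rng)
    ref_len = lens[idx]
    if model.fragment_mean < 2 * rl:
        import warnings

        warnings.warn("fragment mean < 2x read length: mates will overlap")
    frag = np.clip(
        np.rint(rng.normal(model.fragment_mean, model.fragment_sd, n_pairs)),
        rl,
        ref_len,
    ).astype(np.int64)
    start = np.floor(rng.random(n_pairs) * (ref_len - frag + 1)).astype(np.int64)
    # interleaved mate placements: (r1 fwd from fragment start, r2 rev from end)
    n_reads = 2 * n_pairs
    ridx = np.repeat(idx, 2)
    rstart = np.empty(n_reads, dtype=np.int64)
    rend = np.empty(n_reads, dtype=np.int64)
    rstart[0::2] = start
    rend[0::2] = start + rl
    rend[1::2] = start + frag
    rstart[1::2] = start + frag - rl
    strand = np.empty(n_reads, dtype=np.int8)
    strand[0::2] = 1
    strand[1::2] = -1
    read_ids = [
        f"sr_{i // 2}/{1 + i % 2}" for i in range(n_reads)
    ]

    rates = (model.mismatch_rate, model.insertion_rate, model.deletion_rate)
    need_seqs = emit == "fastq"
    if need_seqs and not spec.sequences:
        raise ValueError("FASTQ emission requires reference sequences")
    templates: list[str] | None = None
    if need_seqs or any(rates):
        templates = []
        seqs = {r: spec.sequences.get(r, "") for r in names}
        for i in range(n_reads):
            ref = seqs[names[ridx[i]]]
            if not ref:
                # rates need template lengths only; synthesize A-run stand-in
                templates.append("A" * int(rend[i] - rstart[i]))
                continue
            t = ref[rstart[i] : rend[i]]
            if strand[i] < 0:
                t = reverse_complement(t)
            templates.append(t)
        edits = _inject_errors_batch(templates, rates, rng)
    else:
        edits = None

    placements = Placements(
        names, ridx, rstart, rend, strand, read_ids, edits
    )
    reads: list[tuple[str, str, str]] = []
    if need_seqs:
        assert templates is not None
        ed = edits or [""] * n_reads
        for i in range(n_reads):
            seq = apply_edits(templates[i], ed[i])
            reads.append((read_ids[i], seq, model.quality_char * len(seq)))
    return ReadSet(reads=reads, placements=placements)


def simulate_long_reads(
    spec: CommunitySpec,
    n_reads: int,
    model: ErrorModel | None = None,
    seed: int = 0,
    emit: str = "fastq",
) -> ReadSet:
    """Simulate single-end long reads with lognormal lengths.

    Inside homopolymer runs of length >= ``model.min_homopolymer`` the
    per-base indel probability switches to ``model.homopolymer_indel_rate``
    (split evenly between insertion and deletion), emulating the elevated
    homopolymer indel error of nanopore sequencing.
    """
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    model = model or ErrorModel.nanopore()
    rng = np.random.default_rng(seed)
    if n_reads == 0:
        return ReadSet(
            reads=[],
            placements=Placements(
                [], np.empty(0, np.int32), np.empty(0, np.int64),
                np.empty(0, np.int64), np.empty(0, np.int8), [], [],
            ),
        )
    names, idx, lens = _draw_refs(spec, n_reads, rng)
    mu = math.log(model.long_read_mean) - model.long_read_sigma**2 / 2
    length = np.rint(rng.lognormal(mu, model.long_read_sigma, n_reads)).astype(
        np.int64
    )
    length = np.clip(length, 50, lens[idx])
    start = np.floor(rng.random(n_reads) * (lens[idx] - length + 1)).astype(np.int64)
    end = start + length
    strand = np.where(rng.random(n_reads) < 0.5, 1, -1).astype(np.int8)
    read_ids = [f"lr_{i}" for i in range(n_reads)]

    # homopolymer masks per reference (template coordinates handled per read)
    masks: dict[str, np.ndarray] = {}
    for r in names:
        seq = spec.sequences.get(r)
        if seq is None:
            raise ValueError("long-read simulation requires reference sequences")
        m = np.zeros(len(seq), dtype=bool)
        for a, b in homopolymer_runs(seq, model.min_homopolymer):
            m[a:b] = True
        masks[r] = m

    base_indel = model.insertion_rate + model.deletion_rate
    hp_rate = model.homopolymer_indel_rate or base_indel
    mm = model.mismatch_rate
    edits: list[str] = []
    reads: list[tuple[str, str, str]] = []
    for i in range(n_reads):
        name = names[idx[i]]
        ref = spec.sequences[name]
        t = ref[start[i] : end[i]]
        hp = masks[name][start[i] : end[i]]
        if strand[i] < 0:
            t = reverse_complement(t)
            hp = hp[::-1]
        n = len(t)
        u = rng.random(n)
        indel_p = np.where(hp, hp_rate, base_indel)
        ops: list[str] = []
        hit = np.nonzero(u < mm + indel_p)[0]
        for pos in hit:
            x = u[pos]
            if x < mm:
                base = "ACGT"[(_CODE[ord(t[pos])] + 1 + int(rng.integers(3))) % 4]
                ops.append(f"{pos}:X:{base}")
            elif x < mm + indel_p[pos] / 2:
                base = "ACGT"[int(rng.integers(4))]
                ops.append(f"{pos}:I:{base}")
            else:
                ops.append(f"{pos}:D:-")
        edit = ",".join(ops)
        edits.append(edit)
        if emit == "fastq":
            seq = apply_edits(t, edit)
            reads.append((read_ids[i], seq, model.quality_char * len(seq)))
    placements = Placements(names, idx, start, end, strand, read_ids, edits)
    return ReadSet(reads=reads, placements=placements)


def simulate_counts(
    spec: CommunitySpec, n_reads: int, seed: int = 0
):
    """Per-reference read counts with Poisson noise (no read placement).

    Counts are independent Poisson draws with mean ``n_reads`` times the
    resolved mass weight -- the count-level shortcut for experiments that
    only consume the count matrix, equivalent in distribution to binning a
    Poisson-sized multinomial read sample.  Returns a pandas Series.
    """
    import pandas as pd

    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    rng = np.random.default_rng(seed)
    names = sorted(spec.weights)
    lam = np.array([spec.weights[r] for r in names]) * n_reads
    return pd.Series(rng.poisson(lam).astype(float), index=names)


def generate_fixture_genomes(
    n: int,
    length_range: tuple[int, int] = (20000, 60000),
    gc_range: tuple[float, float] = (0.20, 0.71),
    seed: int = 0,
    homopolymer_every: int = 5000,
) -> dict[str, str]:
    """Generate synthetic source genomes for design and simulation tests.

    Stands in for finished microbial reference genomes, mirroring their GC
    spread: each genome's target GC is drawn uniformly in ``gc_range`` and
    realized by biased base sampling.  Homopolymer runs of 6-12 bp are
    planted roughly every ``homopolymer_every`` bases so error-model and
    annotation code paths always have substrate.  Deterministic per seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = gc_range
    if not 0.0 < lo <= hi < 1.0:
        raise ValueError("gc_range must lie inside (0, 1)")
    rng = np.random.default_rng(seed)
    width = max(2, len(str(n)))
    genomes: dict[str, str] = {}
    for g in range(n):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        gc = float(rng.uniform(lo, hi))
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        codes = rng.choice(4, size=length, p=p)
        seq = np.frombuffer(b"ACGT", dtype=np.uint8)[codes].copy()
        if homopolymer_every:
            n_runs = max(1, length // homopolymer_every)
            for _ in range(n_runs):
                run_len = int(rng.integers(6, 13))
                pos = int(rng.integers(0, length - run_len))
                seq[pos : pos + run_len] = ord("ACGT"[int(rng.integers(4))])
        genomes[f"genome_{g + 1:0{width}d}"] = seq.tobytes().decode("ascii")
    return genomes
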