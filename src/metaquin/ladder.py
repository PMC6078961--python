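"""Ladder quantification and quality-control statistics.

Per-reference coverage summaries feed the spike-in diagnostics: the ladder
regression of log2 fold-coverage on log2 input concentration (slope ~1 and
high R^2 indicate quantitative sequencing), the limit of detection and
dynamic range of the concentration ladder, GC/length bias profiles,
sequencing error-rate estimation stratified by homopolymer context, and
saturation-curve fitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .design import homopolymer_runs
from .mixtures import MixtureSpec
from .simulate import Placements

__all__ = [
    "CoverageSummary",
    "LadderFit",
    "DetectionSummary",
    "BiasProfile",
    "ErrorRateReport",
    "SaturationFit",
    "coverage_summary",
    "fit_ladder",
    "detection_limits",
    "bias_profile",
    "annotate_homopolymers",
    "error_rate_report",
    "welch_t_test",
    "fit_richards",
    "n50",
]


@dataclass
class CoverageSummary:
    """Per-reference read counts, mean fold-coverage and breadth."""

    table: pd.DataFrame  # index ref_id; read_count, mean_depth, breadth, detected

    def __getitem__(self, ref_id: str) -> pd.Series:
        return self.table.loc[ref_id]

    @property
    def ref_ids(self) -> list[str]:
        return list(self.table.index)


@dataclass(frozen=True)
class LadderFit:
    slope: float
    slope_se: float
    intercept: float
    r_squared: float
    n_used: int
    excluded: tuple[str, ...] = ()


@dataclass
class DetectionSummary:
    n_detected: int
    lod: float | None  # attomoles/uL; None when the top point is undetected
    dynamic_range: float | None
    per_point: pd.DataFrame  # point, concentration, n, n_detected, fraction
    flagged: str = ""


@dataclass
class BiasProfile:
    covariate: str  # "gc" or "length"
    table: pd.DataFrame  # ref_id, covariate value, obs_over_exp (mean 1)
    excluded: tuple[str, ...] = ()


@dataclass
class ErrorRateReport:
    mismatch_rate: float
    insertion_rate: float
    deletion_rate: float
    aligned_bases: int
    stratum: pd.DataFrame  # index {homopolymer, other}: bases, indels, indel_rate
    welch: tuple[float, float, float]  # (t, df, p) homopolymer vs other per-sequin


@dataclass(frozen=True)
class SaturationFit:
    A: float
    D: float
    B: float
    C: float
    E: float
    rss: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        return _richards(np.asarray(x, dtype=float), self.A, self.D, self.B,
                         self.C, self.E)


def _iter_sam(path) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray, dict[str, int]]:
    """Primary alignments from a SAM/BAM file as placement-like columns."""
    import pysam

    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        names = list(af.references)
        lengths = {n: l for n, l in zip(af.references, af.lengths)}
        name_idx = {n: i for i, n in enumerate(names)}
        refs, starts, ends = [], [], []
        for rec in af:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            refs.append(name_idx[rec.reference_name])
            starts.append(rec.reference_start)
            ends.append(rec.reference_end)
    return (
        names,
        np.asarray(refs, dtype=np.int32),
        np.asarray(starts, dtype=np.int64),
        np.asarray(ends, dtype=np.int64),
        lengths,
    )


def coverage_summary(
    placements: Placements | str,
    ref_lengths: dict[str, int],
) -> CoverageSummary:
    """Summarise read count, mean depth and breadth per reference.

    Accepts either ground-truth placements or a SAM/BAM path (primary
    alignments only).  mean_depth is total aligned bases over reference
    length; breadth is the fraction of positions covered at least once,
    computed from the union of alignment intervals.
    """
    if isinstance(placements, (str, bytes)) or hasattr(placements, "__fspath__"):
        names, ridx, start, end, sam_lengths = _iter_sam(placements)
        ref_lengths = {**sam_lengths, **ref_lengths}
    else:
        names = placements.ref_names
        ridx, start, end = placements.ref_idx, placements.start, placements.end
    unknown = [n for n in names if n not in ref_lengths]
    if unknown:
        raise ValueError(f"unknown reference ids: {', '.join(sorted(unknown))}")

    all_ids = list(ref_lengths)
    lens = np.array([ref_lengths[r] for r in all_ids], dtype=np.int64)
    id_index = {r: i for i, r in enumerate(all_ids)}
    # map placement ref indices onto the full reference list
    remap = np.array([id_index[n] for n in names], dtype=np.int64) if names else \
        np.empty(0, dtype=np.int64)
    gidx = remap[ridx] if len(ridx) else np.empty(0, dtype=np.int64)

    read_count = np.bincount(gidx, minlength=len(all_ids))
    aligned = np.bincount(gidx, weights=(end - start).astype(float),
                          minlength=len(all_ids))
    # breadth via a global difference array over concatenated coordinates
    offsets = np.concatenate([[0], np.cumsum(lens)])
    total = int(offsets[-1])
    diff = np.zeros(total + 1, dtype=np.int64)
    if len(gidx):
        np.add.at(diff, offsets[gidx] + start, 1)
        np.add.at(diff, offsets[gidx] + end, -1)
    depth = np.cumsum(diff[:-1])
    covered = depth > 0
    breadth = np.array(
        [covered[offsets[i]: offsets[i + 1]].sum() for i in range(len(all_ids))],
        dtype=float,
    ) / lens
    table = pd.DataFrame(
        {
            "read_count": read_count,
            "mean_depth": aligned / lens,
            "breadth": breadth,
            "detected": read_count >= 1,
        },
        index=pd.Index(all_ids, name="ref_id"),
    )
    return CoverageSummary(table=table)


def fit_ladder(cov: CoverageSummary, mix: MixtureSpec) -> LadderFit:
    """OLS of log2(mean fold-coverage) on log2(input concentration).

    Zero-coverage sequins are excluded (and listed) rather than imputed.
    """
    conc = mix.concentrations
    ids = [i for i in conc if i in cov.table.index]
    depth = cov.table.loc[ids, "mean_depth"].to_numpy()
    used = depth > 0
    excluded = tuple(np.asarray(ids)[~used])
    if used.sum() < 3:
        raise ValueError("fewer than 3 sequins with nonzero coverage")
    x = np.log2([conc[i] for i, u in zip(ids, used) if u])
    y = np.log2(depth[used])
    res = stats.linregress(x, y)
    return LadderFit(
        slope=float(res.slope),
        slope_se=float(res.stderr),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_used=int(used.sum()),
        excluded=excluded,
    )


def detection_limits(cov: CoverageSummary, mix: MixtureSpec) -> DetectionSummary:
    """Limit of detection and dynamic range of the ladder.

    LoD is the smallest point concentration c such that every sequin at every
    point with concentration >= c is detected (has at least one read); the
    dynamic range is the top concentration divided by the LoD.  An undetected
    sequin at the top point leaves the LoD undefined and flags the summary.
    """
    detected = cov.table["detected"]
    rows = []
    points = sorted({e.point_index for e in mix.entries})
    for p in points:
        members = mix.point_members(p)
        n_det = sum(bool(detected.get(e.sequin_id, False)) for e in members)
        rows.append(
            {
                "point": p,
                "concentration": members[0].concentration,
                "n": len(members),
                "n_detected": n_det,
                "fraction": n_det / len(members),
            }
        )
    per_point = pd.DataFrame(rows).set_index("point")
    n_detected = int(
        sum(bool(detected.get(e.sequin_id, False)) for e in mix.entries)
    )
    lod = None
    for p in points:  # top (most concentrated) first
        if per_point.loc[p, "n_detected"] == per_point.loc[p, "n"]:
            lod = float(per_point.loc[p, "concentration"])
        else:
            break
    flagged = ""
    if lod is None:
        flagged = "top ladder point not fully detected: LoD undefined"
    top = float(per_point["concentration"].max())
    return DetectionSummary(
        n_detected=n_detected,
        lod=lod,
        dynamic_range=(top / lod) if lod else None,
        per_point=per_point,
        flagged=flagged,
    )


def bias_profile(
    cov: CoverageSummary, mix: MixtureSpec, covariate: str = "gc"
) -> BiasProfile:
    """Observed/expected coverage per sequin against GC or length.

    Expected depth is proportional to input concentration (this controls for
    the orders of magnitude spanned by the staggered ladder); the profile is
    normalized so its mean is 1.
    """
    if covariate not in ("gc", "length"):
        raise ValueError("covariate must be 'gc' or 'length'")
    rows = []
    excluded = []
    for e in mix.entries:
        if e.concentration <= 0:
            excluded.append(e.sequin_id)
            continue
        depth = float(cov.table.loc[e.sequin_id, "mean_depth"])
        rows.append(
            {
                "ref_id": e.sequin_id,
                covariate: e.gc if covariate == "gc" else e.length,
                "obs_over_exp": depth / e.concentration,
            }
        )
    df = pd.DataFrame(rows)
    mean = df["obs_over_exp"].mean()
    if mean <= 0:
        raise ValueError("no coverage anywhere in the ladder")
    df["obs_over_exp"] /= mean
    df = df.sort_values(covariate).reset_index(drop=True)
    return BiasProfile(covariate=covariate, table=df, excluded=tuple(excluded))


def annotate_homopolymers(sequence: str, min_len: int = 6) -> list[tuple[int, int]]:
    """Maximal homopolymer runs of length >= min_len, 0-based half-open."""
    return homopolymer_runs(sequence, min_len)


def welch_t_test(x, y) -> tuple[float, float, float]:
    """Unpaired t-test with Welch's correction (Satterthwaite df).

    Returns (t, df, two-sided p).  Degenerate pooled variance yields
    (0, nan, 1) with a warning rather than an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both samples need at least 2 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx + vy == 0:
        import warnings

        warnings.warn("degenerate variance in Welch t-test; returning p = 1")
        return (0.0, float("nan"), 1.0)
    sx, sy = vx / len(x), vy / len(y)
    t = (x.mean() - y.mean()) / math.sqrt(sx + sy)
    df = (sx + sy) ** 2 / (sx**2 / (len(x) - 1) + sy**2 / (len(y) - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return (float(t), float(df), float(p))


def _ref_stratum_bases(
    placements: Placements,
    ref_lengths: dict[str, int],
    masks: dict[str, np.ndarray],
) -> pd.DataFrame:
    """Per-reference aligned bases and indel counts split by homopolymer context."""
    cum = {r: np.concatenate([[0], np.cumsum(m.astype(np.int64))]) for r, m in masks.items()}
    rows: dict[str, dict[str, float]] = {
        r: {"hp_bases": 0, "other_bases": 0, "hp_indels": 0, "other_indels": 0,
            "mismatches": 0, "insertions": 0, "deletions": 0}
        for r in ref_lengths
    }
    edits = placements.edits or [""] * len(placements)
    for i in range(len(placements)):
        name = placements.ref_names[placements.ref_idx[i]]
        s, e = int(placements.start[i]), int(placements.end[i])
        row = rows[name]
        hp = int(cum[name][e] - cum[name][s])
        row["hp_bases"] += hp
        row["other_bases"] += (e - s) - hp
        if not edits[i]:
            continue
        mask = masks[name]
        minus = placements.strand[i] < 0
        for op in edits[i].split(","):
            pos_s, kind, _ = op.split(":")
            pos = int(pos_s)
            refpos = (e - 1 - pos) if minus else (s + pos)
            refpos = min(max(refpos, 0), len(mask) - 1)
            if kind == "X":
                row["mismatches"] += 1
                continue
            row["insertions" if kind == "I" else "deletions"] += 1
            if mask[refpos]:
                row["hp_indels"] += 1
            else:
                row["other_indels"] += 1
    return pd.DataFrame(rows).T


def error_rate_report(
    placements: Placements,
    references: dict[str, str],
    min_homopolymer: int = 6,
) -> ErrorRateReport:
    """Estimate per-base error rates from truth placements with edit logs.

    Rates are counts over aligned bases, overall and stratified into
    homopolymer runs (>= ``min_homopolymer`` bp) versus other sequence; the
    Welch t-test compares per-reference homopolymer and non-homopolymer
    indel rates.
    """
    ref_lengths = {r: len(s) for r, s in references.items()}
    masks = {}
    for r, s in references.items():
        m = np.zeros(len(s), dtype=bool)
        for a, b in homopolymer_runs(s, min_homopolymer):
            m[a:b] = True
        masks[r] = m
    per_ref = _ref_stratum_bases(placements, ref_lengths, masks)
    total_bases = float(per_ref[["hp_bases", "other_bases"]].to_numpy().sum())
    if total_bases == 0:
        raise ValueError("zero aligned bases")
    mismatch = per_ref["mismatches"].sum() / total_bases
    insertion = per_ref["insertions"].sum() / total_bases
    deletion = per_ref["deletions"].sum() / total_bases

    stratum = pd.DataFrame(
        {
            "bases": [per_ref["hp_bases"].sum(), per_ref["other_bases"].sum()],
            "indels": [per_ref["hp_indels"].sum(), per_ref["other_indels"].sum()],
        },
        index=["homopolymer", "other"],
    )
    stratum["indel_rate"] = np.where(
        stratum["bases"] > 0, stratum["indels"] / stratum["bases"], 0.0
    )

    usable = per_ref[(per_ref["hp_bases"] > 0) & (per_ref["other_bases"] > 0)]
    if len(usable) >= 2:
        hp_rates = usable["hp_indels"] / usable["hp_bases"]
        other_rates = usable["other_indels"] / usable["other_bases"]
        welch = welch_t_test(hp_rates, other_rates)
    else:
        welch = (float("nan"), float("nan"), float("nan"))
    return ErrorRateReport(
        mismatch_rate=float(mismatch),
        insertion_rate=float(insertion),
        deletion_rate=float(deletion),
        aligned_bases=int(total_bases),
        stratum=stratum,
        welch=welch,
    )


def _richards(x, A, D, B, C, E):
    # +/-50 keeps (1+e^z)^E finite for E <= 10 while the tails are already
    # flat to ~1e-22
    z = np.clip(-B * (np.asarray(x, dtype=float) - C), -50.0, 50.0)
    return A + (D - A) / (1.0 + np.exp(z)) ** E


def fit_richards(x, y, seed: int = 0, n_starts: int = 20) -> SaturationFit:
    """Least-squares fit of the five-parameter logistic (Richards) curve.

    y = A + (D - A) / (1 + exp(-B (x - C)))**E with the asymptotes A and D
    clamped to [0, 1] (the response is a fraction).  Multi-start optimization
    from seeded random initial points; non-convergence from every start is
    reported as a flagged fit with infinite residual sum of squares.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 6:
        raise ValueError("need at least 6 points for a 5-parameter fit")
    if np.any((y < 0) | (y > 1)):
        raise ValueError("y must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    def residuals(theta):
        return _richards(x, *theta) - y

    lo = np.array([0.0, 0.0, 1e-3, x.min() - 2 * np.ptp(x) - 1.0, 1e-2])
    hi = np.array([1.0, 1.0, 50.0, x.max() + 2 * np.ptp(x) + 1.0, 10.0])
    best = None
    starts = [
        np.array([max(y.min(), 0.0), min(y.max(), 1.0), 1.0, float(np.median(x)), 1.0])
    ]
    for _ in range(n_starts - 1):
        starts.append(lo + rng.random(5) * (hi - lo))
    for theta0 in starts:
        try:
            res = optimize.least_squares(
                residuals, np.clip(theta0, lo, hi), bounds=(lo, hi), max_nfev=2000
            )
        except Exception:
            continue
        rss = float(np.sum(res.fun**2))
        if best is None or rss < best[1]:
            best = (res.x, rss)
    if best is None:
        return SaturationFit(math.nan, math.nan, math.nan, math.nan, math.nan,
                             math.inf)
    theta, rss = best
    return SaturationFit(*(float(v) for v in theta), rss=rss)


def n50(lengths) -> int:
    """Largest L such that contigs of length >= L sum to >= half the total."""
    arr = sorted(int(v) for v in lengths)
    if not arr:
        raise ValueError("empty length list")
    if any(v <= 0 for v in arr):
        raise ValueError("lengths must be positive")
    half = sum(arr) / 2
    acc = 0
    for v in reversed(arr):
        acc += v
        if acc >= half:
            return v
    return arr[0]
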