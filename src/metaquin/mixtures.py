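"""Staggered concentration ladders and paired fold-change mixtures.

Mix A is the quantification ladder: sequins pooled at twofold serial
dilutions across 16 concentration points, at least 5 sequins per point, each
point spanning the GC range.  Mix B realises known log2 fold changes against
Mix A for a subset of sequins while the rest stay equimolar, giving built-in
positive and negative controls for differential-abundance analysis.

The default Mix B scheme swaps concentrations between sequins that sit
``magnitude`` ladder points apart, so Mix B is itself an exact ladder with
the same point sizes and the same total mass as Mix A.  Mass preservation is
what lets equimolar sequins read out as unchanged under plain library-size
normalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import SequinRecord

__all__ = [
    "MixtureEntry",
    "MixtureSpec",
    "MixPairSpec",
    "build_ladder",
    "build_mix_pair",
    "expected_lfc",
    "ROLE_FOLD_CHANGE",
    "ROLE_EQUIMOLAR",
]

ROLE_FOLD_CHANGE = "fold_change"
ROLE_EQUIMOLAR = "equimolar"


@dataclass(frozen=True)
class MixtureEntry:
    sequin_id: str
    concentration: float  # attomoles/uL
    point_index: int
    length: int = 0
    gc: float = float("nan")


@dataclass
class MixtureSpec:
    name: str
    entries: list[MixtureEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.sequin_id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate sequin ids in mixture")
        if any(e.concentration <= 0 for e in self.entries):
            raise ValueError("concentrations must be strictly positive")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def concentrations(self) -> dict[str, float]:
        return {e.sequin_id: e.concentration for e in self.entries}

    @property
    def n_points(self) -> int:
        return max(e.point_index for e in self.entries) + 1

    def point_members(self, point: int) -> list[MixtureEntry]:
        return [e for e in self.entries if e.point_index == point]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [e.sequin_id for e in self.entries],
                "length": [e.length for e in self.entries],
                "gc": [e.gc for e in self.entries],
                "point": [e.point_index for e in self.entries],
                "concentration_amol_per_ul": [e.concentration for e in self.entries],
            }
        )

    def validate_ladder(self, dilution: float) -> None:
        """Check exact geometric spacing of the point concentrations."""
        concs = {}
        for e in self.entries:
            concs.setdefault(e.point_index, set()).add(e.concentration)
        for point, vals in concs.items():
            if len(vals) != 1:
                raise ValueError(f"point {point} has mixed concentrations")
        levels = [next(iter(concs[p])) for p in sorted(concs)]
        for hi, lo in zip(levels, levels[1:]):
            if hi != lo * dilution:
                raise ValueError("ladder is not an exact geometric series")


@dataclass
class MixPairSpec:
    mix_a: MixtureSpec
    mix_b: MixtureSpec
    roles: dict[str, str]  # sequin id -> fold_change | equimolar

    def __post_init__(self) -> None:
        a_ids = set(self.mix_a.concentrations)
        b_ids = set(self.mix_b.concentrations)
        if a_ids != b_ids:
            raise ValueError("Mix A and Mix B must contain the same sequins")
        if set(self.roles) != a_ids:
            raise ValueError("roles must cover every sequin")

    @property
    def n_fold_change(self) -> int:
        return sum(r == ROLE_FOLD_CHANGE for r in self.roles.values())

    @property
    def n_equimolar(self) -> int:
        return sum(r == ROLE_EQUIMOLAR for r in self.roles.values())

    def to_frame(self) -> pd.DataFrame:
        df = self.mix_a.to_frame().rename(
            columns={"concentration_amol_per_ul": "concentration_a"}
        )
        conc_b = self.mix_b.concentrations
        df["concentration_b"] = [conc_b[i] for i in df["id"]]
        df["expected_lfc"] = np.log2(df["concentration_b"] / df["concentration_a"])
        df["role"] = [self.roles[i] for i in df["id"]]
        return df


def build_ladder(
    sequins: list[SequinRecord],
    n_points: int = 16,
    dilution: float = 2.0,
    anchor: float = 60.0,
    name: str = "MixA",
) -> MixtureSpec:
    """Assign sequins to a staggered concentration ladder.

    Point ``i`` (0 = most concentrated) has concentration
    ``anchor * dilution**(n_points - 1 - i)``; the default anchor of
    60 attomoles/uL therefore places the lowest point at 60 amol/uL.  Group
    sizes are floor(n / n_points) with the remainder going one each to the
    most concentrated points.  Sequins are sorted by GC (ties broken by id)
    and dealt round-robin across points so every point spans the GC range.
    """
    if n_points < 2:
        raise ValueError("need at least 2 ladder points")
    if len(sequins) < n_points:
        raise ValueError(
            f"{len(sequins)} sequins cannot fill {n_points} ladder points"
        )
    base = len(sequins) // n_points
    remainder = len(sequins) % n_points
    capacity = [base + (1 if p < remainder else 0) for p in range(n_points)]

    ordered = sorted(sequins, key=lambda s: (s.gc, s.id))
    entries: list[MixtureEntry] = []
    it = iter(ordered)
    for round_idx in range(max(capacity)):
        for point in range(n_points):
            if round_idx < capacity[point]:
                s = next(it)
                entries.append(
                    MixtureEntry(
                        sequin_id=s.id,
                        concentration=anchor * dilution ** (n_points - 1 - point),
                        point_index=point,
                        length=s.length,
                        gc=s.gc,
                    )
                )
    entries.sort(key=lambda e: (e.point_index, e.sequin_id))
    return MixtureSpec(name=name, entries=entries)


def build_mix_pair(
    mix_a: MixtureSpec,
    n_fold_change: int = 50,
    lfc_magnitudes: tuple[int, ...] = (1, 2, 3),
    rng_seed: int = 0,
    name_b: str = "MixB",
) -> MixPairSpec:
    """Derive Mix B from Mix A by swapping concentrations between sequins.

    ``n_fold_change`` sequins (default 50) change abundance between mixtures;
    the remainder (36 with the default 86-sequin ladder) stay equimolar.
    Changes come in up/down pairs of equal magnitude: a sequin at point p
    swaps concentration with one at point p+magnitude, so signs are balanced
    exactly and per-magnitude counts are as even as the pair count allows
    (8/8/9 pairs for 50 sequins and magnitudes {1, 2, 3}).  Pairs are spread
    across the ladder deterministically given the seed, and within each
    chosen point pair the two swapped sequins are picked to keep the total
    DNA mass (sum of concentration x length) of Mix B as close to Mix A as
    the available lengths allow, so the two mixtures remain directly
    comparable under plain library-size normalization.
    """
    if not lfc_magnitudes:
        raise ValueError("lfc_magnitudes must not be empty")
    if n_fold_change > len(mix_a):
        raise ValueError("n_fold_change exceeds mixture size")
    if n_fold_change % 2:
        raise ValueError("n_fold_change must be even (changes come in swap pairs)")
    n_pairs = n_fold_change // 2
    mags = sorted(lfc_magnitudes)
    base, rem = divmod(n_pairs, len(mags))
    # remainder pairs go to the largest magnitudes
    mag_counts = {
        m: base + (1 if i >= len(mags) - rem else 0) for i, m in enumerate(mags)
    }

    n_points = mix_a.n_points
    dilution_steps: dict[str, float] = {}
    by_point: dict[int, list[MixtureEntry]] = {}
    for e in mix_a.entries:
        by_point.setdefault(e.point_index, []).append(e)
    for members in by_point.values():
        members.sort(key=lambda e: e.sequin_id)
    available = {p: list(members) for p, members in by_point.items()}

    rng = np.random.default_rng(rng_seed)
    point_pairs: list[tuple[int, int]] = []
    reserved: dict[int, int] = {p: 0 for p in range(n_points)}
    # largest magnitudes first: they have the fewest feasible point pairs
    for mag in sorted(mag_counts, reverse=True):
        for _ in range(mag_counts[mag]):
            feasible = [
                p
                for p in range(n_points - mag)
                if len(available.get(p, ())) - reserved[p] > 0
                and len(available.get(p + mag, ())) - reserved[p + mag] > 0
            ]
            if not feasible:
                raise ValueError(
                    f"cannot place a +/-{mag} swap: ladder points exhausted"
                )
            # spread pairs across the ladder: prefer the points with the most
            # unassigned sequins, break ties with the seeded RNG
            depth = [
                len(available[p]) - reserved[p]
                + len(available[p + mag]) - reserved[p + mag]
                for p in feasible
            ]
            top = [p for p, d in zip(feasible, depth) if d == max(depth)]
            p = top[int(rng.integers(len(top)))]
            point_pairs.append((p, p + mag))
            reserved[p] += 1
            reserved[p + mag] += 1

    # assign members largest concentrations first, greedily cancelling the
    # running mass imbalance sum((c_hi - c_lo) * (len_lo - len_hi))
    swaps: list[tuple[MixtureEntry, MixtureEntry]] = []
    delta = 0.0
    for p_hi, p_lo in sorted(point_pairs):
        best: tuple[float, str, str, MixtureEntry, MixtureEntry] | None = None
        for hi in available[p_hi]:
            for lo in available[p_lo]:
                d = (hi.concentration - lo.concentration) * (hi.length - lo.length)
                key = (abs(delta + d), hi.sequin_id, lo.sequin_id, hi, lo)
                if best is None or key[:3] < best[:3]:
                    best = key
        assert best is not None
        _, _, _, hi, lo = best
        available[p_hi].remove(hi)
        available[p_lo].remove(lo)
        delta += (hi.concentration - lo.concentration) * (hi.length - lo.length)
        swaps.append((hi, lo))

    conc_b = dict(mix_a.concentrations)
    point_b = {e.sequin_id: e.point_index for e in mix_a.entries}
    roles = {e.sequin_id: ROLE_EQUIMOLAR for e in mix_a.entries}
    for hi, lo in swaps:
        conc_b[hi.sequin_id], conc_b[lo.sequin_id] = lo.concentration, hi.concentration
        point_b[hi.sequin_id], point_b[lo.sequin_id] = lo.point_index, hi.point_index
        roles[hi.sequin_id] = ROLE_FOLD_CHANGE
        roles[lo.sequin_id] = ROLE_FOLD_CHANGE

    entries_b = [
        MixtureEntry(
            sequin_id=e.sequin_id,
            concentration=conc_b[e.sequin_id],
            point_index=point_b[e.sequin_id],
            length=e.length,
            gc=e.gc,
        )
        for e in mix_a.entries
    ]
    entries_b.sort(key=lambda e: (e.point_index, e.sequin_id))
    mix_b = MixtureSpec(name=name_b, entries=entries_b)
    return MixPairSpec(mix_a=mix_a, mix_b=mix_b, roles=roles)


def expected_lfc(pair: MixPairSpec) -> pd.DataFrame:
    """Expected log2 fold change (B vs A) per sequin; observed column empty."""
    conc_a = pair.mix_a.concentrations
    conc_b = pair.mix_b.concentrations
    ids = sorted(conc_a)
    return pd.DataFrame(
        {
            "sequin_id": ids,
            "expected_lfc": [math.log2(conc_b[i] / conc_a[i]) for i in ids],
            "observed_lfc": [float("nan")] * len(ids),
            "role": [pair.roles[i] for i in ids],
        }
    )
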