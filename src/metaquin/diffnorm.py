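"""Fold-change assessment, control-based diagnostics and normalization.

The designed mixtures give every count matrix a built-in truth set: sequins
with fold-change roles are known positives and equimolar sequins are known
negatives.  This module computes observed log2 fold changes, runs a simple
per-feature differential test (Welch on log2 normalized counts; the control
framework is test-agnostic, so a dispersion-modelling count test can be
swapped in), derives sensitivity/specificity and
ROC curves from the control roles, and implements three normalization
schemes: conventional (genome size + library depth), absolute (dividing
fractional abundances by the per-sample sequin read fraction), and
control-based factor normalization (RUVg-style SVD on negative-control
features), plus upper-quartile factors and RLE/CV diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .ladder import welch_t_test
from .mixtures import ROLE_EQUIMOLAR, ROLE_FOLD_CHANGE

__all__ = [
    "DiffTestResult",
    "RocResult",
    "observed_lfc",
    "diff_test",
    "roc_curve",
    "normalize_conventional",
    "sequin_read_fraction",
    "normalize_absolute",
    "ruv_normalize",
    "rle_summary",
    "group_cv",
    "upper_quartile_factors",
    "benjamini_hochberg",
]


def _check_counts(counts: pd.DataFrame) -> None:
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")


def library_size_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Total-count scaling to the mean library size."""
    _check_counts(counts)
    depth = counts.sum(axis=0)
    if (depth <= 0).any():
        raise ValueError("every sample needs a positive library size")
    return counts * (depth.mean() / depth)


def observed_lfc(
    counts: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    normalize: bool = True,
) -> pd.DataFrame:
    """log2(mean normalized count in B / mean in A) per feature.

    Features with zero mean in either group get NaN and are flagged in the
    ``missing`` column.
    """
    if not group_a or not group_b:
        raise ValueError("both groups need at least one sample")
    norm = library_size_normalize(counts) if normalize else counts
    mean_a = norm[group_a].mean(axis=1)
    mean_b = norm[group_b].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2(mean_b / mean_a)
    missing = (mean_a == 0) | (mean_b == 0)
    lfc[missing] = np.nan
    return pd.DataFrame(
        {"observed_lfc": lfc, "mean_a": mean_a, "mean_b": mean_b,
         "missing": missing}
    )


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values."""
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DiffTestResult:
    table: pd.DataFrame  # per feature: observed_lfc, p, p_adj, significant, role
    alpha: float
    sensitivity: float = float("nan")
    specificity: float = float("nan")


def diff_test(
    counts: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    roles: dict[str, str] | None = None,
    alpha: float = 0.05,
    pseudocount: float = 0.5,
) -> DiffTestResult:
    """Per-feature Welch t-test on log2(normalized count + pseudocount).

    With control roles supplied, sensitivity is the fraction of
    fold-change-role features with BH-adjusted p below alpha and specificity
    the fraction of equimolar-role features at or above it.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 replicates per group")
    norm = library_size_normalize(counts)
    loga = np.log2(norm[group_a].to_numpy() + pseudocount)
    logb = np.log2(norm[group_b].to_numpy() + pseudocount)
    pvals = np.empty(len(counts))
    tvals = np.empty(len(counts))
    for i in range(len(counts)):
        t, _, p = welch_t_test(logb[i], loga[i])
        tvals[i], pvals[i] = t, p
    p_adj = benjamini_hochberg(pvals)
    lfc = observed_lfc(counts, group_a, group_b)["observed_lfc"]
    table = pd.DataFrame(
        {
            "observed_lfc": lfc,
            "t": tvals,
            "p": pvals,
            "p_adj": p_adj,
            "significant": p_adj < alpha,
        },
        index=counts.index,
    )
    sens = spec = float("nan")
    if roles:
        table["role"] = [roles.get(f, "") for f in counts.index]
        pos = table[table["role"] == ROLE_FOLD_CHANGE]
        neg = table[table["role"] == ROLE_EQUIMOLAR]
        if len(pos):
            sens = float(pos["significant"].mean())
        if len(neg):
            spec = float((~neg["significant"]).mean())
    return DiffTestResult(table=table, alpha=alpha, sensitivity=sens,
                          specificity=spec)


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    by_magnitude: dict[float, "RocResult"] = field(default_factory=dict)


def roc_curve(
    scores,
    labels,
    magnitudes=None,
) -> RocResult:
    """ROC over a p-value threshold sweep (smaller score = more positive).

    Tied scores advance both axes simultaneously.  AUC by the trapezoid
    rule.  With per-feature |expected LFC| magnitudes supplied, positives
    are additionally stratified per magnitude against all negatives.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(scores, kind="stable")
    s, lab = scores[order], labels[order]
    fpr = [0.0]
    tpr = [0.0]
    i = 0
    while i < len(s):
        j = i
        while j < len(s) and s[j] == s[i]:
            j += 1
        tp_step = lab[i:j].sum()
        fp_step = (j - i) - tp_step
        tpr.append(tpr[-1] + tp_step / n_pos)
        fpr.append(fpr[-1] + fp_step / n_neg)
        i = j
    fpr_a, tpr_a = np.asarray(fpr), np.asarray(tpr)
    auc = float(np.trapezoid(tpr_a, fpr_a))
    result = RocResult(fpr=fpr_a, tpr=tpr_a, auc=auc)
    if magnitudes is not None:
        mags = np.asarray(magnitudes, dtype=float)
        for m in sorted(set(np.abs(mags[labels]))):
            keep = (~labels) | (np.abs(mags) == m)
            result.by_magnitude[float(m)] = roc_curve(scores[keep], labels[keep])
    return result


def normalize_conventional(
    counts: pd.DataFrame,
    genome_sizes: dict[str, float],
    community_ids: list[str] | None = None,
    library_depths: pd.Series | None = None,
) -> pd.DataFrame:
    """Fractional abundance after genome-size and library-depth normalization.

    Per sample: abundance_i = (count_i / size_i) / sum over community
    features of (count_j / size_j), so community fractions sum to 1.  This is
    within-sample relative abundance: it is exactly invariant to the total
    DNA load of the sample.
    """
    _check_counts(counts)
    missing = [f for f in counts.index if f not in genome_sizes]
    if missing:
        raise ValueError(f"no genome size for: {', '.join(map(str, missing))}")
    sizes = pd.Series({f: float(genome_sizes[f]) for f in counts.index})
    if (sizes <= 0).any():
        raise ValueError("genome sizes must be positive")
    depths = counts.sum(axis=0) if library_depths is None else library_depths
    if (depths <= 0).any():
        raise ValueError("library depths must be positive")
    per_size = counts.div(depths, axis=1).div(sizes, axis=0)
    community = community_ids if community_ids is not None else list(counts.index)
    denom = per_size.loc[community].sum(axis=0)
    if (denom <= 0).any():
        raise ValueError("zero community total in at least one sample")
    return per_size.div(denom, axis=1)


def sequin_read_fraction(counts: pd.DataFrame, sequin_ids: list[str]) -> pd.Series:
    """phi per sample: fraction of all reads that aligned to sequins."""
    _check_counts(counts)
    present = [s for s in sequin_ids if s in counts.index]
    if not present:
        raise ValueError("no sequin features in the count matrix")
    if len(present) == len(counts):
        raise ValueError("no community features in the count matrix")
    total = counts.sum(axis=0)
    if (total <= 0).any():
        raise ValueError("zero total reads in at least one sample")
    return counts.loc[present].sum(axis=0) / total


def normalize_absolute(
    fractional: pd.DataFrame, phi: pd.Series
) -> pd.DataFrame:
    """Absolute-abundance index: fractional abundance / sequin read fraction.

    With a fixed-mass spike, phi is inversely proportional to the sample's
    total DNA load, so dividing by it rescales each sample to a common
    absolute reference point; ratios of the index between samples estimate
    absolute fold changes.
    """
    phi = phi.reindex(fractional.columns)
    if phi.isna().any() or (phi <= 0).any():
        raise ValueError("phi must be positive for every sample")
    return fractional.div(phi, axis=1)


def ruv_normalize(
    log_counts: pd.DataFrame,
    control_ids: list[str],
    k: int = 1,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Remove unwanted variation estimated from negative-control features.

    Factor analysis on the sample-by-control matrix of centered control
    log-counts: W is the first k left singular vectors; the unwanted
    component W @ alpha (alpha fit per feature by least squares, with
    intercept) is subtracted from every feature.  k = 0 is the identity.
    Returns (adjusted log-counts, W).
    """
    controls = [c for c in control_ids if c in log_counts.index]
    if k < 0:
        raise ValueError("k must be >= 0")
    if k >= max(len(controls), 1):
        raise ValueError("k must be smaller than the number of controls")
    n_samples = log_counts.shape[1]
    if k == 0:
        return log_counts.copy(), np.zeros((n_samples, 0))
    # samples x controls, each control centered across samples
    Z = log_counts.loc[controls].to_numpy().T
    Z = Z - Z.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(Z, full_matrices=False)
    W = u[:, :k]  # samples x k
    design = np.column_stack([np.ones(n_samples), W])
    Y = log_counts.to_numpy().T  # samples x features
    coef, *_ = np.linalg.lstsq(design, Y, rcond=None)
    unwanted = W @ coef[1:, :]  # samples x features
    adjusted = (Y - unwanted).T
    return pd.DataFrame(adjusted, index=log_counts.index,
                        columns=log_counts.columns), W


def rle_summary(counts: pd.DataFrame, pseudocount: float = 0.0) -> pd.DataFrame:
    """Relative log expression per sample: median and IQR of
    log2(count / feature-wise median across samples).

    All-zero feature rows (no defined reference median) are dropped.
    """
    _check_counts(counts)
    vals = counts.to_numpy(dtype=float) + pseudocount
    keep = vals.sum(axis=1) > 0
    vals = vals[keep]
    ref = np.median(vals, axis=1)
    ok = ref > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        logratio = np.log2(vals[ok] / ref[ok, None])
    logratio = np.where(np.isfinite(logratio), logratio, np.nan)
    med = np.nanmedian(logratio, axis=0)
    q75 = np.nanpercentile(logratio, 75, axis=0)
    q25 = np.nanpercentile(logratio, 25, axis=0)
    return pd.DataFrame(
        {"median": med, "iqr": q75 - q25}, index=counts.columns
    )


def group_cv(values: pd.DataFrame, groups: dict[str, list[str]]) -> pd.DataFrame:
    """Coefficient of variation (sample SD / mean) per feature per group."""
    out = {}
    for gname, samples in groups.items():
        if len(samples) < 2:
            raise ValueError(f"group {gname!r} needs >= 2 replicates")
        sub = values[samples]
        mean = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            out[gname] = (sd / mean).where(mean != 0)
    return pd.DataFrame(out)


def upper_quartile_factors(counts: pd.DataFrame) -> pd.Series:
    """Per-sample 75th percentile of nonzero counts (UQ scaling factors)."""
    _check_counts(counts)
    factors = {}
    for col in counts.columns:
        nz = counts[col][counts[col] > 0]
        if nz.empty:
            raise ValueError(f"sample {col!r} has no nonzero counts")
        factors[col] = float(np.percentile(nz, 75))
    return pd.Series(factors)
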