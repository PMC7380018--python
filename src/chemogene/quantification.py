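"""Transcript abundance (RPKM), assembly N50/N90, and qPCR expression analysis.

RPKM normalises a gene's uniquely mapped read count C by gene length L (in
bases) and library size N (total uniquely mapped reads):

    RPKM = 1e6 * C * 1000 / (N * L)

Relative expression between tissues uses the comparative 2^(-ddCT) method:
technical replicates are averaged to one CT, dCT = CT_target - CT_reference
within a sample, ddCT subtracts the calibrator tissue's dCT, and the fold
change is 2^(-ddCT).  Biological replicates propagate to the standard error.
The method assumes near-equal amplification efficiencies of target and
reference; that assumption is checked by the dilution-slope test (|slope| of
dCT against log10 dilution must be < 0.1) and by standard-curve
efficiencies (amplification factor E = 10^(-1/slope) of CT against log10
template, required to be at least 1.90 where perfect doubling is 2.0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

SLOPE_LIMIT = 0.1  # |dCT slope| below this validates the ddCT assumption
MIN_EFFICIENCY = 1.90  # amplification factor threshold from standard curves


@dataclass
class FoldChange:
    gene: str
    tissue: str
    fold: float  # mean of per-biological-replicate folds
    se: float  # standard error over biological replicates
    folds: tuple[float, ...]  # per-biological-replicate folds


def rpkm(C: float, N: float, L: float) -> float:
    """Reads per kilobase per million mapped reads."""
    if L <= 0:
        raise ValueError(f"gene length must be positive, got {L}")
    if N <= 0:
        raise ValueError(f"library size must be positive, got {N}")
    if C < 0:
        raise ValueError(f"read count must be non-negative, got {C}")
    return 1e6 * C * 1000 / (N * L)


def rpkm_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`rpkm` to a count table with columns gene, count, length,
    library_size."""
    out = counts.copy()
    out["rpkm"] = [
        rpkm(c, n, l)
        for c, n, l in zip(counts["count"], counts["library_size"], counts["length"])
    ]
    return out


def nxx(lengths, fraction: float) -> int:
    """N50/N90-style statistic: sort lengths descending and return the
    smallest length at which the cumulative sum first reaches
    ``fraction * total``."""
    lengths = np.asarray(list(lengths))
    if lengths.size == 0:
        raise ValueError("empty length list")
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    if (lengths <= 0).any():
        raise ValueError("lengths must be positive")
    ordered = np.sort(lengths)[::-1]
    target = fraction * ordered.sum()
    cum = np.cumsum(ordered)
    return int(ordered[np.searchsorted(cum, target)])


def _mean_ct(df: pd.DataFrame, gene: str, tissue: str) -> pd.Series:
    """Average technical replicates to one CT per biological replicate."""
    sub = df[(df["gene"] == gene) & (df["tissue"] == tissue)]
    if sub.empty:
        raise KeyError(f"no CT observations for gene {gene!r}, tissue {tissue!r}")
    return sub.groupby("bio_rep")["ct"].mean()


def ddct_fold(
    cts: pd.DataFrame,
    gene: str,
    tissue: str,
    reference: str,
    calibrator: str,
) -> FoldChange:
    """Relative expression of ``gene`` in ``tissue`` vs the calibrator tissue.

    ``cts`` has columns gene, tissue, bio_rep, tech_rep, ct.  Technical
    replicates are averaged first; the per-biological-replicate dCT is
    paired with the same biological replicate in the calibrator when the ids
    overlap, otherwise against the calibrator's mean dCT.
    """
    try:
        ref_t = _mean_ct(cts, reference, tissue)
        ref_c = _mean_ct(cts, reference, calibrator)
    except KeyError as exc:
        raise KeyError(f"missing reference gene data: {exc}") from exc
    tgt_t = _mean_ct(cts, gene, tissue)
    tgt_c = _mean_ct(cts, gene, calibrator)

    dct_t = (tgt_t - ref_t).dropna()
    dct_c = (tgt_c - ref_c).dropna()
    shared = dct_t.index.intersection(dct_c.index)
    if len(shared) == len(dct_t):
        ddct = dct_t.loc[shared] - dct_c.loc[shared]
    else:
        ddct = dct_t - dct_c.mean()
    folds = np.power(2.0, -ddct.to_numpy(dtype=float))
    se = float(np.std(folds, ddof=1) / np.sqrt(len(folds))) if len(folds) > 1 else 0.0
    return FoldChange(gene, tissue, float(folds.mean()), se, tuple(folds))


def dilution_slope(
    dilution_factors, dct_values
) -> tuple[float, bool]:
    """Least-squares slope of dCT against log10 dilution, and the pass flag.

    A near-zero slope (|slope| < 0.1) shows the target and reference genes
    amplify with near-equal efficiency, validating the ddCT comparison.
    """
    x = np.log10(np.asarray(list(dilution_factors), dtype=float))
    y = np.asarray(list(dct_values), dtype=float)
    if len(x) < 3:
        raise ValueError(f"need at least 3 dilution points, got {len(x)}")
    if not np.all(np.diff(x) > 0):
        raise ValueError("dilution factors must be strictly increasing")
    slope = float(stats.linregress(x, y).slope)
    return slope, abs(slope) < SLOPE_LIMIT


def efficiency_from_curve(log10_template, ct_values) -> tuple[float, bool]:
    """Amplification factor E = 10^(-1/slope) from a standard curve.

    ``slope`` is the least-squares slope of CT against log10 template
    amount; perfect doubling gives slope -3.3219 and E = 2.0.  The flag
    marks E >= 1.90.
    """
    x = np.asarray(list(log10_template), dtype=float)
    y = np.asarray(list(ct_values), dtype=float)
    if len(x) < 3:
        raise ValueError(f"need at least 3 points, got {len(x)}")
    slope = float(stats.linregress(x, y).slope)
    if slope >= 0:
        raise ValueError(f"standard-curve slope must be negative, got {slope:.3g}")
    eff = 10 ** (-1 / slope)
    return float(eff), eff >= MIN_EFFICIENCY


class DegenerateVarianceError(ValueError):
    """All groups identical (zero within-group variance everywhere)."""


def tukey_letters(
    groups: dict[str, "np.ndarray | list[float]"], alpha: float = 0.05
) -> dict[str, str]:
    """Compact letter display from one-way ANOVA + all-pairs Tukey HSD.

    Groups sharing no significant pairwise difference share a letter;
    letters are assigned greedily from the highest group mean.  Requires at
    least two groups with at least two replicates each.
    """
    names = list(groups)
    data = [np.asarray(groups[k], dtype=float) for k in names]
    if len(names) < 2 or any(len(d) < 2 for d in data):
        raise ValueError("need >= 2 groups with >= 2 replicates each")
    if all(np.ptp(d) == 0 for d in data) and len({d[0] for d in data}) == 1:
        # no variation anywhere: everything shares one letter
        return {k: "a" for k in names}
    if all(np.ptp(d) == 0 for d in data):
        raise DegenerateVarianceError(
            "zero within-group variance; Tukey HSD undefined"
        )
    res = stats.tukey_hsd(*data)
    k = len(names)
    differs = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            differs[i, j] = differs[j, i] = res.pvalue[i, j] < alpha

    # One letter per maximal clique of the non-significance graph, so two
    # groups share a letter exactly when Tukey finds no difference between
    # them.  Letters run a, b, ... from the clique holding the highest mean.
    cliques: list[tuple[int, ...]] = []
    for mask in range(1, 1 << k):
        members = [i for i in range(k) if mask >> i & 1]
        if any(differs[i, j] for i in members for j in members if i < j):
            continue
        cliques.append(tuple(members))
    maximal = [
        c for c in cliques
        if not any(set(c) < set(d) for d in cliques)
    ]
    maximal.sort(key=lambda c: -max(data[i].mean() for i in c))
    letters = "abcdefghijklmnopqrstuvwxyz"
    assignment: dict[int, list[str]] = {i: [] for i in range(k)}
    for li, clique in enumerate(maximal):
        for i in clique:
            assignment[i].append(letters[li])
    return {names[i]: "".join(sorted(assignment[i])) for i in range(k)}
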