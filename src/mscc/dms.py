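"""Differential-methylation calling: per-site Welch t tests between two
conditions on normalized digestion frequencies, Benjamini–Hochberg FDR
control, and directional classification.

Because tag abundance is inversely proportional to methylation, a site whose
digestion frequency FALLS under treatment has GAINED methylation
("methylated"); a rise means loss ("demethylated").  Site-specific digestion
biases are shared between conditions and cancel in the per-site contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

VAR_FLOOR = 1e-8  # guards zero-variance integer ties at low depth


@dataclass
class FilterPolicy:
    """Which sites are deep enough to test.

    ``min_reads`` in ``any-library`` scope (the default) keeps a site if any
    single library reaches the threshold; ``every-library`` requires all.
    Detection (for reporting) means at least one read in every library.
    """

    min_reads: float = 20
    scope: str = "any-library"

    def __post_init__(self) -> None:
        if self.min_reads < 0:
            raise ValueError("min_reads must be >= 0")
        if self.scope not in ("any-library", "every-library"):
            raise ValueError(f"unknown scope {self.scope!r}")


def filter_sites(
    matrix: pd.DataFrame, policy: FilterPolicy | None = None
) -> tuple[pd.Index, dict[str, int]]:
    """Sites meeting the depth policy, plus detected/tested counts."""
    policy = policy or FilterPolicy()
    detected = (matrix > 0).all(axis=1)
    if policy.scope == "any-library":
        tested = (matrix >= policy.min_reads).any(axis=1)
    else:
        tested = (matrix >= policy.min_reads).all(axis=1)
    return matrix.index[tested], {
        "total": len(matrix),
        "detected": int(detected.sum()),
        "tested": int(tested.sum()),
    }


def welch_test(control, treated) -> tuple[float, float, float]:
    """Welch's unequal-variance t test on one site.

    t = (mean_c - mean_t) / sqrt(s2_c/n_c + s2_t/n_t), degrees of freedom by
    Welch–Satterthwaite, two-sided p from the t distribution.  Sample
    variances are floored at 1e-8.
    """
    c = np.asarray(control, dtype=float)
    t_ = np.asarray(treated, dtype=float)
    if len(c) < 2 or len(t_) < 2:
        raise ValueError("need >= 2 replicates per group")
    t, df, p = _welch_arrays(c[None, :], t_[None, :])
    return float(t[0]), float(df[0]), float(p[0])


def _welch_arrays(c: np.ndarray, t: np.ndarray):
    vc = np.maximum(c.var(axis=1, ddof=1), VAR_FLOOR)
    vt = np.maximum(t.var(axis=1, ddof=1), VAR_FLOOR)
    nc, nt = c.shape[1], t.shape[1]
    se2 = vc / nc + vt / nt
    tstat = (c.mean(axis=1) - t.mean(axis=1)) / np.sqrt(se2)
    df = se2**2 / ((vc / nc) ** 2 / (nc - 1) + (vt / nt) ** 2 / (nt - 1))
    p = 2 * stats.t.sf(np.abs(tstat), df)
    return tstat, df, p


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_dms(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    fdr: float = 0.05,
    policy: FilterPolicy | None = None,
    log1p: bool = False,
) -> pd.DataFrame:
    """Per-site Welch test + BH-FDR + direction over a normalized matrix.

    ``design`` needs columns ``library`` and ``condition`` with exactly two
    conditions; the first in order of appearance is treated as control.
    Returns a frame with means, t, df, p, q, direction and passed_filter
    for every site (untested sites carry NaN statistics).
    """
    conds = list(dict.fromkeys(design["condition"]))
    if len(conds) != 2:
        raise ValueError(f"need exactly 2 conditions, got {conds}")
    libs_c = design.loc[design["condition"] == conds[0], "library"].tolist()
    libs_t = design.loc[design["condition"] == conds[1], "library"].tolist()
    if len(libs_c) < 2 or len(libs_t) < 2:
        raise ValueError("need >= 2 replicates per condition")
    keep, counts = filter_sites(matrix, policy)
    sub = matrix.loc[keep]
    c = sub[libs_c].to_numpy(dtype=float)
    t = sub[libs_t].to_numpy(dtype=float)
    if log1p:
        c, t = np.log1p(c), np.log1p(t)
    tstat, df, p = _welch_arrays(c, t)
    q = bh_fdr(p)
    out = pd.DataFrame(
        {
            "mean_control": np.full(len(matrix), np.nan),
            "mean_treated": np.full(len(matrix), np.nan),
            "t": np.nan,
            "df": np.nan,
            "p": np.nan,
            "q": np.nan,
            "direction": "none",
            "passed_filter": False,
        },
        index=matrix.index,
    )
    out.loc[keep, "mean_control"] = c.mean(axis=1)
    out.loc[keep, "mean_treated"] = t.mean(axis=1)
    out.loc[keep, "t"] = tstat
    out.loc[keep, "df"] = df
    out.loc[keep, "p"] = p
    out.loc[keep, "q"] = q
    out.loc[keep, "passed_filter"] = True
    out.attrs["filter_counts"] = counts
    return classify_direction(out, fdr)


def classify_direction(table: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Label significant sites by direction of the methylation change.

    Digestion falls when methylation rises, so ``mean_treated < mean_control``
    at a significant site is a gain ("methylated") and the converse a loss
    ("demethylated").  Exact mean ties stay "none" with a warning.
    """
    table = table.copy()
    sig = table["q"] < threshold
    down = table["mean_treated"] < table["mean_control"]
    up = table["mean_treated"] > table["mean_control"]
    table["direction"] = "none"
    table.loc[sig & down, "direction"] = "methylated"
    table.loc[sig & up, "direction"] = "demethylated"
    ties = sig & ~down & ~up
    if ties.any():
        warnings.warn(f"{int(ties.sum())} significant sites with exactly tied means")
    return table


def replicate_r2(
    matrix: pd.DataFrame, n_sites: int = 1200, seed: int | np.random.Generator = 0
) -> pd.DataFrame:
    """All-vs-all Pearson r² between libraries on a random site subset.

    A fixed-size random selection of sites (1,200 by default) keeps the
    reproducibility diagnostic cheap and comparable across datasets.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 libraries")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_sites >= len(matrix):
        if n_sites > len(matrix):
            warnings.warn(
                f"requested {n_sites} sites but only {len(matrix)} available; using all"
            )
        sub = matrix
    else:
        idx = rng.choice(len(matrix), size=n_sites, replace=False)
        sub = matrix.iloc[np.sort(idx)]
    r = np.corrcoef(sub.to_numpy(dtype=float).T)
    return pd.DataFrame(r**2, index=matrix.columns, columns=matrix.columns)


def within_between_r2(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    n_sites: int = 1200,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Mean within-condition and between-condition pairwise r²."""
    r2 = replicate_r2(matrix, n_sites=n_sites, seed=seed)
    cond = dict(zip(design["library"], design["condition"]))
    within, between = [], []
    libs = list(r2.columns)
    for i, a in enumerate(libs):
        for b in libs[i + 1 :]:
            (within if cond[a] == cond[b] else between).append(r2.loc[a, b])
    return float(np.mean(within)), float(np.mean(between))
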