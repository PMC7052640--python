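"""Population-level analysis of measurement tables.

Operates on a tidy table (rows = cells) holding the 18 sub- and
suprathreshold measurements plus ``sector`` and ``cell_id`` columns, with
NaN marking unavailable measurements (e.g. AP features of a cell that never
spiked). Provides the variability metrics used to quantify heterogeneity
(SD, IQR, CV), parametric and nonparametric sector comparisons, pairwise
Pearson correlation matrices with the weak-correlation band |R| < 0.4, and
PCA on the standardized measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError

#: The 18 analysis measurements, in presentation order.
MEASUREMENT_COLUMNS = [
    "V_RMP", "R_in", "S_alpha", "R_in_bar", "sag", "f_R", "Z_max", "Q", "Phi_L",
    "V_th", "V_AP_peak", "V_AP", "T_APHW", "dVdt_max", "dVdt_min",
    "T_1AP", "T_1ISI", "f_250",
]

UNITS = {
    "V_RMP": "mV", "R_in": "MOhm", "S_alpha": "", "R_in_bar": "MOhm",
    "sag": "%", "f_R": "Hz", "Z_max": "MOhm", "Q": "", "Phi_L": "rad.Hz",
    "V_th": "mV", "V_AP_peak": "mV", "V_AP": "mV", "T_APHW": "ms",
    "dVdt_max": "V/s", "dVdt_min": "V/s", "T_1AP": "ms", "T_1ISI": "ms",
    "f_50": "Hz", "f_100": "Hz", "f_150": "Hz", "f_200": "Hz", "f_250": "Hz",
    "rheobase": "pA", "V_hold": "mV",
}

#: correlations with |R| below this are "weak"
WEAK_R = 0.4


class Variability(NamedTuple):
    SD: float
    IQR: float
    CV: float


@dataclass
class GroupComparison:
    """Omnibus and pairwise sector comparisons for one measurement column."""

    column: str
    groups: dict                       # sector -> values used
    anova_p: float
    kruskal_p: float
    anova_F: float
    kruskal_H: float
    pairwise_wilcoxon: dict            # (sector_a, sector_b) -> p
    pairwise_tukey: dict               # (sector_a, sector_b) -> p


@dataclass
class CorrelationResult:
    """Pairwise-complete Pearson correlations over the measurement columns."""

    R: pd.DataFrame
    P: pd.DataFrame
    n_used: pd.DataFrame
    weak_mask: pd.DataFrame            # True where |R| < WEAK_R
    r_values: np.ndarray               # off-diagonal upper-triangle R values
    flagged_constant: list = field(default_factory=list)


@dataclass
class PCAResult:
    loadings: pd.DataFrame             # columns PC1.. ; rows = measurements
    explained_fraction: np.ndarray
    scores: pd.DataFrame               # per-cell scores with sector labels
    standardization: pd.DataFrame      # per-column mean/SD used for z-scoring


def variability_metrics(values: Sequence[float]) -> Variability:
    """Sample SD (n−1), IQR (linear-interpolation quantiles), and signed CV.

    The CV carries the sign of the mean, so voltage measurements (negative
    means) report negative CVs. Requires at least two non-missing values.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 2:
        raise InsufficientDataError("variability_metrics needs >= 2 non-missing values")
    sd = float(np.std(x, ddof=1))
    q1, q3 = np.percentile(x, [25, 75])
    mean = float(np.mean(x))
    cv = sd / mean if mean != 0 else np.nan
    return Variability(SD=sd, IQR=float(q3 - q1), CV=cv)


def compare_groups(table: pd.DataFrame, column: str) -> GroupComparison:
    """Parametric and nonparametric sector comparisons for one measurement.

    Runs one-way ANOVA and Kruskal–Wallis omnibus tests plus pairwise
    Wilcoxon rank-sum and Tukey HSD for every sector pair. All statistics and
    p-values are reported; no thresholding is applied here.
    """
    groups = {}
    for sector, sub in table.groupby("sector", observed=True):
        vals = sub[column].dropna().to_numpy()
        if len(vals) < 3:
            raise InsufficientDataError(
                f"sector {sector!r} has only {len(vals)} values for {column!r}"
            )
        groups[sector] = vals
    if len(groups) < 2:
        raise InsufficientDataError(f"need >= 2 sectors with data for {column!r}")
    names = sorted(groups)
    arrays = [groups[s] for s in names]
    F, p_anova = stats.f_oneway(*arrays)
    H, p_kw = stats.kruskal(*arrays)
    wilcoxon, tukey = {}, {}
    hsd = stats.tukey_hsd(*arrays)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            pair = (names[i], names[j])
            # Wilcoxon rank-sum == Mann-Whitney U; exact null for small n
            wilcoxon[pair] = float(
                stats.mannwhitneyu(arrays[i], arrays[j], alternative="two-sided").pvalue
            )
            tukey[pair] = float(hsd.pvalue[i, j])
    return GroupComparison(
        column=column, groups=groups,
        anova_p=float(p_anova), kruskal_p=float(p_kw),
        anova_F=float(F), kruskal_H=float(H),
        pairwise_wilcoxon=wilcoxon, pairwise_tukey=tukey,
    )


def correlation_matrix(
    table: pd.DataFrame, columns: Sequence[str] = MEASUREMENT_COLUMNS
) -> CorrelationResult:
    """Pairwise-complete Pearson R and two-sided p over the measurement columns.

    Entries with fewer than 3 complete pairs, and any constant column, yield
    NaN (constant columns are also listed in ``flagged_constant``). The
    ``weak_mask`` marks |R| < 0.4 and ``r_values`` collects the off-diagonal
    R values for the correlation-histogram insets.
    """
    cols = [c for c in columns if c in table.columns]
    k = len(cols)
    R = np.full((k, k), np.nan)
    P = np.full((k, k), np.nan)
    N = np.zeros((k, k), dtype=int)
    flagged = []
    data = {c: table[c].to_numpy(dtype=float) for c in cols}
    for i, ci in enumerate(cols):
        xi = data[ci]
        ok_i = ~np.isnan(xi)
        if np.nanstd(xi) == 0:
            flagged.append(ci)
        for j in range(i, k):
            xj = data[cols[j]]
            ok = ok_i & ~np.isnan(xj)
            N[i, j] = N[j, i] = int(ok.sum())
            if i == j:
                R[i, i] = 1.0
                P[i, i] = 0.0
                continue
            if ok.sum() < 3 or np.std(xi[ok]) == 0 or np.std(xj[ok]) == 0:
                continue
            r, p = stats.pearsonr(xi[ok], xj[ok])
            R[i, j] = R[j, i] = r
            P[i, j] = P[j, i] = p
    Rdf = pd.DataFrame(R, index=cols, columns=cols)
    iu = np.triu_indices(k, 1)
    return CorrelationResult(
        R=Rdf,
        P=pd.DataFrame(P, index=cols, columns=cols),
        n_used=pd.DataFrame(N, index=cols, columns=cols),
        weak_mask=Rdf.abs() < WEAK_R,
        r_values=R[iu][~np.isnan(R[iu])],
        flagged_constant=flagged,
    )


def pca_embed(
    table: pd.DataFrame,
    n_components: int = 3,
    columns: Sequence[str] = MEASUREMENT_COLUMNS,
) -> PCAResult:
    """PCA on z-scored complete-case measurements via the correlation matrix.

    Components are eigenvectors of the correlation matrix of the complete
    cases, ordered by decreasing eigenvalue; explained fractions are
    eigenvalues over the total variance (all components). The sign of each
    component is fixed so its largest-magnitude loading is positive. Scores
    are returned for the first ``n_components`` with the sector labels kept.
    """
    cols = [c for c in columns if c in table.columns]
    complete = table.dropna(subset=cols)
    if len(complete) < n_components:
        raise InsufficientDataError(
            f"only {len(complete)} complete cases for {n_components} components"
        )
    X = complete[cols].to_numpy(dtype=float)
    sd0 = X.std(axis=0, ddof=1)
    if np.any(sd0 == 0):
        # a constant measurement (e.g. Phi_L identically zero in a noiseless
        # low-pass population) carries no variance: drop it from the embedding
        cols = [c for c, s in zip(cols, sd0) if s > 0]
        X = complete[cols].to_numpy(dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    Z = (X - mean) / sd
    corr = np.corrcoef(Z, rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    for j in range(evecs.shape[1]):
        if evecs[np.argmax(np.abs(evecs[:, j])), j] < 0:
            evecs[:, j] = -evecs[:, j]
    frac = evals / evals.sum()
    names = [f"PC{i+1}" for i in range(len(cols))]
    scores = pd.DataFrame(
        Z @ evecs[:, :n_components],
        columns=names[:n_components],
        index=complete.index,
    )
    if "sector" in complete.columns:
        scores["sector"] = complete["sector"].to_numpy()
    return PCAResult(
        loadings=pd.DataFrame(evecs, index=cols, columns=names),
        explained_fraction=frac,
        scores=scores,
        standardization=pd.DataFrame({"mean": mean, "sd": sd}, index=cols),
    )


def summary_table(table: pd.DataFrame, columns: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-sector mean, SE, n, SD, IQR, CV for each measurement (the published-table layout)."""
    if columns is None:
        columns = [c for c in MEASUREMENT_COLUMNS if c in table.columns]
    rows = []
    for sector, sub in table.groupby("sector", observed=True):
        for col in columns:
            x = sub[col].dropna().to_numpy(dtype=float)
            if len(x) < 2:
                continue
            v = variability_metrics(x)
            rows.append({
                "sector": sector, "measurement": col, "unit": UNITS.get(col, ""),
                "mean": np.mean(x), "se": v.SD / np.sqrt(len(x)), "n": len(x),
                "sd": v.SD, "iqr": v.IQR, "cv": v.CV,
            })
    return pd.DataFrame(rows)
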