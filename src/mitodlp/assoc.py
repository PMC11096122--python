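"""Heteroplasmy / copy-number association statistics.

The central statistic is a stratified, weighted concordance (a Kendall-tau
style rank statistic): within each stratum (sequencing library), every pair
of cells is concordant when heteroplasmy and mtDNA copy number order agree,
discordant when they disagree, and ties contribute half. Per-stratum
concordance fractions are combined with per-stratum weights (the number of
cells in the library), the null variance is the Kendall null variance mapped
to the concordance scale and combined with squared weights, and z/p follow a
normal reference:

    c_s = (#concordant + 0.5 #ties) / #pairs
    c   = sum_s w_s c_s / sum_s w_s,     c_scaled = 2c - 1
    Var0(c_s) = [2(2n_s + 5) / (9 n_s (n_s - 1))] / 4
    z = (c - 1/2) / sqrt(sum_s w_s^2 Var0(c_s) / (sum_s w_s)^2)

A within-stratum permutation null is provided as the calibration oracle for
the analytic variance. Observation filters mirror the variant-inclusion
rules of the analysis (min alternate reads, heteroplasmy window, range).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

import statsmodels.api as sm


@dataclass
class ConcordanceResult:
    c: float
    c_scaled: float
    variance: float
    z: float
    p: float
    n_obs: int
    n_strata: int
    q: float = float("nan")
    reason: str = ""

    @property
    def defined(self) -> bool:
        return np.isfinite(self.c)


def concordance_filters(
    het: pd.DataFrame,
    alt: pd.DataFrame,
    cn: pd.Series,
    strata: pd.Series,
    min_alt: int = 10,
    lo: float = 0.05,
    hi: float = 0.95,
    min_range: float = 0.15,
) -> dict[object, pd.DataFrame]:
    """Build per-variant observation sets for the concordance test.

    ``het``/``alt`` are cell x variant matrices (heteroplasmy and alternate
    read counts), ``cn`` and ``strata`` per-cell. An observation survives when
    its alternate reads are >= ``min_alt`` and its heteroplasmy is neither
    below ``lo`` nor above ``hi`` (the endpoints themselves are retained); a
    variant is kept only when the surviving heteroplasmy range (max - min) is
    >= ``min_range``. Stratum weights are the number of gated cells per
    stratum, counted before per-variant filtering.
    """
    weights = strata.value_counts().to_dict()
    out: dict[object, pd.DataFrame] = {}
    for v in het.columns:
        h = het[v]
        a = alt[v]
        keep = h.notna() & (a >= min_alt) & ~((h < lo) | (h > hi))
        if keep.sum() < 2:
            continue
        hv = h[keep]
        if hv.max() - hv.min() < min_range:
            continue
        obs = pd.DataFrame(
            {
                "h": hv,
                "y": cn.loc[hv.index],
                "stratum": strata.loc[hv.index],
            }
        )
        obs["weight"] = obs["stratum"].map(weights).astype(float)
        out[v] = obs.reset_index(drop=True)
    return out


def _pair_concordance(h: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """(concordance fraction with half-ties, n pairs) over all pairs."""
    n = len(h)
    sh = np.sign(h[:, None] - h[None, :])
    sy = np.sign(y[:, None] - y[None, :])
    prod = sh * sy
    iu = np.triu_indices(n, k=1)
    p = prod[iu]
    n_pairs = p.size
    concordant = int((p > 0).sum())
    ties = int((p == 0).sum())
    return (concordant + 0.5 * ties) / n_pairs, n_pairs


def _null_var(n: int) -> float:
    # Kendall tau null variance, mapped to the concordance (c = (tau+1)/2) scale
    return (2.0 * (2 * n + 5) / (9.0 * n * (n - 1))) / 4.0


def stratified_concordance(obs: pd.DataFrame) -> ConcordanceResult:
    """Stratified weighted concordance of ``h`` against ``y``.

    ``obs`` columns: ``h``, ``y``, ``stratum``, ``weight`` (one weight per
    stratum). Strata with fewer than 2 observations are excluded; if none
    remain the result is NaN-flagged with a reason rather than raising.
    """
    parts = []
    n_obs = 0
    for s, grp in obs.groupby("stratum", sort=True):
        if len(grp) < 2:
            continue
        w = float(grp["weight"].iloc[0])
        c_s, _ = _pair_concordance(grp["h"].to_numpy(float), grp["y"].to_numpy(float))
        parts.append((w, c_s, len(grp)))
        n_obs += len(grp)
    if not parts:
        return ConcordanceResult(
            c=float("nan"), c_scaled=float("nan"), variance=float("nan"), z=float("nan"),
            p=float("nan"), n_obs=int(len(obs)), n_strata=0, reason="all_strata_degenerate",
        )
    ws = np.array([p[0] for p in parts])
    cs = np.array([p[1] for p in parts])
    ns = np.array([p[2] for p in parts])
    c = float(np.sum(ws * cs) / np.sum(ws))
    variance = float(np.sum(ws**2 * np.array([_null_var(n) for n in ns])) / np.sum(ws) ** 2)
    z = (c - 0.5) / np.sqrt(variance) if variance > 0 else float("nan")
    p = float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else float("nan")
    return ConcordanceResult(
        c=c, c_scaled=2.0 * c - 1.0, variance=variance, z=float(z), p=p,
        n_obs=n_obs, n_strata=len(parts),
    )


def permutation_null(obs: pd.DataFrame, n_perm: int = 999, seed: int = 0) -> float:
    """Empirical two-tailed p for the concordance by permuting y within strata."""
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    observed = stratified_concordance(obs)
    if not observed.defined:
        return float("nan")
    t_obs = abs(observed.c - 0.5)
    hits = 0
    work = obs.copy()
    groups = [np.flatnonzero((obs["stratum"] == s).to_numpy()) for s in obs["stratum"].unique()]
    y = obs["y"].to_numpy(float)
    for _ in range(n_perm):
        y_perm = y.copy()
        for idx in groups:
            y_perm[idx] = y[rng.permutation(idx)]
        work["y"] = y_perm
        c_star = stratified_concordance(work).c
        if abs(c_star - 0.5) >= t_obs - 1e-12:
            hits += 1
    return (1.0 + hits) / (n_perm + 1.0)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def concordance_table(per_variant_obs: dict, n_perm: int | None = None, seed: int = 0) -> pd.DataFrame:
    """Concordance results for every variant, with BH-adjusted q-values."""
    rows = []
    for v, obs in per_variant_obs.items():
        res = stratified_concordance(obs)
        row = {
            "variant": v, "n_obs": res.n_obs, "n_strata": res.n_strata, "c": res.c,
            "c_scaled": res.c_scaled, "variance": res.variance, "z": res.z, "p": res.p,
            "reason": res.reason,
        }
        if n_perm:
            row["p_perm"] = permutation_null(obs, n_perm=n_perm, seed=seed)
        rows.append(row)
    table = pd.DataFrame(rows)
    if len(table):
        ok = table["p"].notna()
        table["q"] = np.nan
        if ok.any():
            table.loc[ok, "q"] = bh_adjust(table.loc[ok, "p"].to_numpy())
    return table


def size_regression(percell: pd.DataFrame, min_cells: int = 3) -> pd.DataFrame:
    """Per-library regression of mtDNA copy number on cell diameter.

    Fits OLS ``cn ~ diameter`` (slope in copies per micron, with 95% CI) and
    the multiple regression ``cn ~ diameter + average_ploidy``; reports the
    Pearson correlation of cn and diameter with its two-sided p, BH-adjusted
    across libraries. Libraries with constant diameter or fewer than
    ``min_cells`` diametered cells are flagged and excluded from BH.
    """
    rows = []
    for lib, grp in percell.groupby("library_id", sort=True):
        g = grp.dropna(subset=["diameter_um", "cn"])
        row: dict = {"library_id": lib, "n": int(len(g))}
        if len(g) < min_cells:
            row["flag"] = "too_few_cells"
            rows.append(row)
            continue
        d = g["diameter_um"].to_numpy(float)
        c = g["cn"].to_numpy(float)
        if np.ptp(d) == 0:
            row["flag"] = "constant_diameter"
            rows.append(row)
            continue
        X = sm.add_constant(d)
        ols = sm.OLS(c, X).fit()
        ci = ols.conf_int()
        r, p = stats.pearsonr(d, c)
        row.update(
            slope=float(ols.params[1]), intercept=float(ols.params[0]),
            slope_ci_lo=float(ci[1][0]), slope_ci_hi=float(ci[1][1]),
            pearson_r=float(r), p=max(float(p), np.finfo(float).tiny), flag="",
        )
        if "average_ploidy" in g.columns and np.ptp(g["average_ploidy"].to_numpy(float)) > 0:
            X2 = sm.add_constant(np.column_stack([d, g["average_ploidy"].to_numpy(float)]))
            ols2 = sm.OLS(c, X2).fit()
            row["slope_diameter_adj"] = float(ols2.params[1])
            row["slope_ploidy"] = float(ols2.params[2])
        rows.append(row)
    table = pd.DataFrame(rows)
    if len(table) and "p" in table.columns:
        ok = table["p"].notna()
        table["q"] = np.nan
        if ok.any():
            table.loc[ok, "q"] = bh_adjust(table.loc[ok, "p"].to_numpy())
    return table
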