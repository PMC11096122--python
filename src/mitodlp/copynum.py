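"""Per-cell nuclear ploidy, mtDNA copy number, MNR, WGD contrasts and
depth-downsampling stability.

Copy number follows the depth-ratio estimator for amplification-free scWGS:

    mtDNA copy number = (mtDNA read depth / nuDNA read depth) x average ploidy

where average ploidy is the mean integer copy-number state over
500-kb-equivalent nuclear bins, and the mtDNA-to-nuDNA ratio (MNR) is the
bare depth ratio — mtDNA copies per average haploid nuclear genome. Baseline
ploidy (the modal bin state) defines the diploid/tetraploid labels used in
whole-genome-doubling contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from mitodlp.simulate import parse_bin_states

WGD_LABELS = {2: "diploid", 3: "triploid", 4: "tetraploid"}


@dataclass
class PloidySummary:
    average_ploidy: float
    baseline_ploidy: int
    wgd_label: str


@dataclass
class MitoCopyNumber:
    cn: float
    mnr: float


def quality_gate(cells: pd.DataFrame, min_quality: float = 0.75) -> tuple[pd.DataFrame, dict]:
    """Keep cells with quality score >= ``min_quality`` (inclusive)."""
    if len(cells) and ((cells["quality"] < 0) | (cells["quality"] > 1)).any():
        raise ValueError("quality scores must lie in [0, 1]")
    kept = cells[cells["quality"] >= min_quality].reset_index(drop=True)
    return kept, {"kept": int(len(kept)), "dropped": int(len(cells) - len(kept))}


def ploidy_summary(bin_states) -> PloidySummary:
    """Average (mean) and baseline (modal) ploidy of one cell's bin states.

    Modal ties break toward the smallest tied state, which is conservative
    against over-calling whole-genome doubling.
    """
    states = np.asarray(bin_states)
    if states.size == 0:
        raise ValueError("bin_states must be nonempty")
    if not np.issubdtype(states.dtype, np.integer):
        raise ValueError("bin_states must be integers")
    values, counts = np.unique(states, return_counts=True)  # values sorted ascending
    baseline = int(values[np.argmax(counts)])
    return PloidySummary(
        average_ploidy=float(states.mean()),
        baseline_ploidy=baseline,
        wgd_label=WGD_LABELS.get(baseline, "other"),
    )


def mito_copy_number(mt_depth: float, nu_depth: float, average_ploidy: float) -> MitoCopyNumber:
    """Depth-ratio copy number: mnr = mt/nu; cn = mnr x average ploidy."""
    if nu_depth <= 0:
        raise ValueError("nu_depth must be positive for copy-number computation")
    if average_ploidy <= 0:
        raise ValueError("average_ploidy must be positive")
    mnr = mt_depth / nu_depth
    return MitoCopyNumber(cn=mnr * average_ploidy, mnr=mnr)


def percell_table(cells: pd.DataFrame) -> pd.DataFrame:
    """Per-cell ploidy and copy-number table from a cells table.

    Adds ``average_ploidy``, ``baseline_ploidy``, ``wgd_label``, ``mnr`` and
    ``cn`` columns; the identity ``cn == mnr * average_ploidy`` holds exactly.
    """
    states = parse_bin_states(cells)
    out = cells.copy()
    summaries = [ploidy_summary(row) for row in states]
    out["average_ploidy"] = [s.average_ploidy for s in summaries]
    out["baseline_ploidy"] = [s.baseline_ploidy for s in summaries]
    out["wgd_label"] = [s.wgd_label for s in summaries]
    out["mnr"] = out["mt_depth"] / out["nu_depth"]
    out["cn"] = out["mnr"] * out["average_ploidy"]
    return out


def mnr_percent_change(mnr_diploid, mnr_tetraploid) -> float:
    """Percent change of median MNR from diploid to tetraploid cells:
    100 x (median(tetraploid) - median(diploid)) / median(diploid)."""
    d = np.asarray(mnr_diploid, float)
    t = np.asarray(mnr_tetraploid, float)
    if d.size == 0 or t.size == 0:
        raise ValueError("both ploidy groups must be nonempty")
    md = float(np.median(d))
    if md == 0:
        raise ValueError("median diploid MNR is zero; percent change undefined")
    return 100.0 * (float(np.median(t)) - md) / md


def ploidy_contrast(
    percell: pd.DataFrame,
    min_group: int = 20,
    alternative: str = "two-sided",
    stratify_by_library: bool = False,
    group_col: str | None = None,
) -> pd.DataFrame:
    """Diploid-vs-tetraploid copy-number and MNR contrasts per sample.

    For each group with at least ``min_group`` cells of each baseline-ploidy
    class: group medians, log2 fold change of CN, percent MNR change, and
    Wilcoxon rank-sum tests of CN (two-sided) and MNR (``alternative``;
    one-sided 'greater' tests an MNR increase in tetraploid cells). Groups
    with too few cells are reported with a skip reason. ``group_col`` can
    override the default sample/library grouping (e.g. to stratify by clone).
    """
    if group_col is None:
        group_col = "library_id" if stratify_by_library else "sample_id"
    rows = []
    for gid, grp in percell.groupby(group_col, sort=True):
        dip = grp[grp["wgd_label"] == "diploid"]
        tet = grp[grp["wgd_label"] == "tetraploid"]
        row = {"group": gid, "n_diploid": len(dip), "n_tetraploid": len(tet)}
        if len(dip) < min_group or len(tet) < min_group:
            row["skip_reason"] = f"fewer than {min_group} cells in a ploidy class"
            rows.append(row)
            continue
        med_cn_d, med_cn_t = dip["cn"].median(), tet["cn"].median()
        row.update(
            median_cn_diploid=med_cn_d,
            median_cn_tetraploid=med_cn_t,
            cn_log2_fold_change=float(np.log2(med_cn_t / med_cn_d)),
            median_mnr_diploid=dip["mnr"].median(),
            median_mnr_tetraploid=tet["mnr"].median(),
            mnr_percent_change=mnr_percent_change(dip["mnr"], tet["mnr"]),
            skip_reason="",
        )
        u_cn = stats.mannwhitneyu(tet["cn"], dip["cn"], alternative="two-sided")
        u_mnr = stats.mannwhitneyu(tet["mnr"], dip["mnr"], alternative=alternative)
        row.update(cn_p=float(u_cn.pvalue), mnr_p=float(u_mnr.pvalue), mnr_alternative=alternative)
        rows.append(row)
    return pd.DataFrame(rows)


def downsample_counts(values, fraction: float, seed: int, counts_per_unit: int = 100):
    """Binomially thin counts (or real depths) to a fraction of the original.

    Integer arrays are thinned read-by-read as Binomial(n, fraction). Real
    arrays are converted to integer read-equivalents at ``counts_per_unit``
    per depth unit, thinned the same way, and scaled back, so the realized
    (stochastic) thinning is preserved. Deterministic given ``seed``;
    ``fraction`` 1 and 0 short-circuit exactly.
    """
    if not 0 <= fraction <= 1:
        raise ValueError(f"fraction must lie in [0, 1], got {fraction}")
    arr = np.asarray(values)
    if fraction == 1.0:
        return arr.copy()
    if fraction == 0.0:
        return np.zeros_like(arr)
    rng = np.random.default_rng(seed)
    if np.issubdtype(arr.dtype, np.integer):
        return rng.binomial(arr, fraction)
    n = np.round(arr * counts_per_unit).astype(np.int64)
    return rng.binomial(n, fraction) / counts_per_unit


def stability_report(full, thinned, name: str = "cn") -> dict:
    """Agreement of paired per-cell estimates before/after thinning.

    Reports Pearson r and median relative error (relative to the full-depth
    value; pairs with a zero full value are excluded from the relative
    error). r is NaN-flagged when fewer than 3 pairs or a constant vector
    makes it undefined.
    """
    f = np.asarray(full, float)
    t = np.asarray(thinned, float)
    if f.shape != t.shape:
        raise ValueError("paired estimate vectors must have equal length")
    out: dict = {"metric": name, "n": int(f.size)}
    if f.size < 3 or np.ptp(f) == 0 or np.ptp(t) == 0:
        out["pearson_r"] = float("nan")
        out["flag"] = "undefined_correlation"
    else:
        out["pearson_r"] = float(stats.pearsonr(f, t)[0])
        out["flag"] = ""
    nz = f != 0
    out["median_relative_error"] = (
        float(np.median(np.abs(t[nz] - f[nz]) / np.abs(f[nz]))) if nz.any() else float("nan")
    )
    return out


def pass_retention(full_records, thinned_records) -> float:
    """Fraction of full-depth PASS variants still PASS after thinning."""
    full_pass = {(r.position, r.alt) for r in full_records if r.is_pass}
    if not full_pass:
        return float("nan")
    thin_pass = {(r.position, r.alt) for r in thinned_records if r.is_pass}
    return len(full_pass & thin_pass) / len(full_pass)
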