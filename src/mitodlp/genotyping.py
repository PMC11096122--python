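"""mtDNA variant filtering and per-cell heteroplasmy genotyping.

Works on pileup-level strand-split allele counts (mapping quality > 20 and
base quality > 20 are assumed to have been applied upstream). The filter
stack retains a variant only when

* pseudo-bulk support has at least two alternate reads on each strand,
* per-cell forward and reverse heteroplasmy agree (Pearson R >= 0.2 across
  cells informative on both strands), and
* the site lies outside the homopolymer blacklist regions 513-525 and
  3105-3109 (1-based, inclusive).

Heteroplasmy is the strand-pooled alternate fraction per cell. The module
also computes strand-resolved trinucleotide substitution spectra on the
circular reference and reference-allele length heteroplasmy at homopolymer
anchors (e.g. the poly-C tract at m.302).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from mitodlp.simulate import BLACKLIST_REGIONS, MT_GENOME_LENGTH

FILTER_NAMES = ("strand_support", "strand_concordance", "blacklist")

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


class CoordinateError(ValueError):
    """A position falls outside the reference contig."""


@dataclass
class VariantRecord:
    """One mtDNA site with its filter outcome."""

    position: int
    ref: str
    alt: str
    var_class: str = "unknown"
    filters_passed: set = field(default_factory=set)
    n_cells_detected: int = 0
    pooled_heteroplasmy: float = float("nan")
    strand_r: float = float("nan")
    fail_reason: str = ""

    @property
    def is_pass(self) -> bool:
        return set(FILTER_NAMES) <= self.filters_passed


def validate_counts(counts: pd.DataFrame) -> None:
    """Check the strand-count table invariants, raising on violation."""
    for col in ("fwd_alt", "rev_alt", "fwd_total", "rev_total"):
        if (counts[col] < 0).any():
            raise ValueError(f"negative read counts in column {col}")
    if (counts["fwd_alt"] > counts["fwd_total"]).any():
        raise ValueError("fwd_alt exceeds fwd_total for some rows")
    if (counts["rev_alt"] > counts["rev_total"]).any():
        raise ValueError("rev_alt exceeds rev_total for some rows")


def strand_support_filter(fwd_alt: int, rev_alt: int, min_reads: int = 2) -> bool:
    """Pseudo-bulk strand support: >= ``min_reads`` alternate reads per strand."""
    if fwd_alt < 0 or rev_alt < 0:
        raise ValueError("read counts must be nonnegative")
    return fwd_alt >= min_reads and rev_alt >= min_reads


def strand_concordance_filter(
    per_cell: pd.DataFrame, min_r: float = 0.2, min_cells: int = 3
) -> tuple[bool, float, str]:
    """Forward/reverse heteroplasmy agreement across cells.

    Cells are informative when both strand totals are positive. Returns
    ``(passed, r, reason)``; an undefined correlation (fewer than two
    informative cells, or zero variance on either strand) fails with a
    reason code rather than raising.
    """
    info = per_cell[(per_cell["fwd_total"] > 0) & (per_cell["rev_total"] > 0)]
    if len(info) < max(min_cells, 2):
        return False, float("nan"), "too_few_informative_cells"
    fwd_h = info["fwd_alt"].to_numpy(float) / info["fwd_total"].to_numpy(float)
    rev_h = info["rev_alt"].to_numpy(float) / info["rev_total"].to_numpy(float)
    if np.ptp(fwd_h) == 0 or np.ptp(rev_h) == 0:
        return False, float("nan"), "zero_variance"
    r = float(np.corrcoef(fwd_h, rev_h)[0, 1])
    if not np.isfinite(r):
        return False, float("nan"), "undefined_correlation"
    return (r >= min_r, r, "" if r >= min_r else "low_strand_correlation")


def blacklist_filter(
    position: int,
    regions: tuple[tuple[int, int], ...] = BLACKLIST_REGIONS,
    reference_length: int = MT_GENOME_LENGTH,
) -> bool:
    """True when ``position`` (1-based) lies outside every blacklist region."""
    if position < 1 or position > reference_length:
        raise CoordinateError(f"position {position} outside 1..{reference_length}")
    return not any(lo <= position <= hi for lo, hi in regions)


def apply_filter_stack(
    counts: pd.DataFrame,
    min_strand_reads: int = 2,
    min_r: float = 0.2,
    min_cells: int = 3,
    regions: tuple[tuple[int, int], ...] = BLACKLIST_REGIONS,
    reference_length: int = MT_GENOME_LENGTH,
    variant_classes: pd.DataFrame | None = None,
) -> list[VariantRecord]:
    """Run every filter on every variant in a long-format count table.

    The three filters are independent predicates of the data, so the PASS set
    does not depend on application order. ``variant_classes`` may map
    positions to functional classes (columns ``position``, ``var_class``).
    """
    validate_counts(counts)
    class_map = {}
    if variant_classes is not None:
        class_map = dict(zip(variant_classes["position"], variant_classes["var_class"]))
    records: list[VariantRecord] = []
    for (pos, ref, alt), grp in counts.groupby(["position", "ref", "alt"], sort=True):
        rec = VariantRecord(
            position=int(pos), ref=str(ref), alt=str(alt), var_class=class_map.get(pos, "unknown")
        )
        pooled_alt = int(grp["fwd_alt"].sum() + grp["rev_alt"].sum())
        pooled_total = int(grp["fwd_total"].sum() + grp["rev_total"].sum())
        rec.pooled_heteroplasmy = pooled_alt / pooled_total if pooled_total else float("nan")
        rec.n_cells_detected = int(((grp["fwd_alt"] + grp["rev_alt"]) > 0).sum())
        if strand_support_filter(int(grp["fwd_alt"].sum()), int(grp["rev_alt"].sum()), min_strand_reads):
            rec.filters_passed.add("strand_support")
        ok, r, reason = strand_concordance_filter(grp, min_r=min_r, min_cells=min_cells)
        rec.strand_r = r
        if ok:
            rec.filters_passed.add("strand_concordance")
        elif reason:
            rec.fail_reason = reason
        if blacklist_filter(int(pos), regions, reference_length):
            rec.filters_passed.add("blacklist")
        records.append(rec)
    return records


def genotype_cells(
    counts: pd.DataFrame, positions: list[int] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell heteroplasmy for the given (PASS) positions.

    Returns ``(heteroplasmy, depth)`` cell x variant matrices; heteroplasmy is
    (fwd_alt + rev_alt) / (fwd_total + rev_total) where the denominator is
    positive, NaN otherwise (depth records the denominator).
    """
    validate_counts(counts)
    sub = counts if positions is None else counts[counts["position"].isin(positions)]
    alt = sub["fwd_alt"] + sub["rev_alt"]
    total = sub["fwd_total"] + sub["rev_total"]
    tmp = pd.DataFrame({"cell_id": sub["cell_id"], "position": sub["position"], "alt": alt, "total": total})
    agg = tmp.groupby(["cell_id", "position"], sort=True).sum()
    depth = agg["total"].unstack(fill_value=0)
    altm = agg["alt"].unstack(fill_value=0)
    het = altm / depth.where(depth > 0)
    return het, depth


def classify_homoplasmy(het: pd.DataFrame, threshold: float = 0.95) -> pd.Series:
    """Label variants homoplasmic (median defined heteroplasmy > threshold) or heteroplasmic."""
    med = het.median(axis=0, skipna=True)
    if med.isna().any():
        bad = list(med.index[med.isna()])
        raise ValueError(f"variants with no defined heteroplasmy entries: {bad}")
    return pd.Series(np.where(med > threshold, "homoplasmic", "heteroplasmic"), index=het.columns)


def _context(reference: str, position: int) -> str:
    """Trinucleotide context around a 1-based position on a circular contig."""
    n = len(reference)
    i = position - 1
    return reference[(i - 1) % n] + reference[i] + reference[(i + 1) % n]


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _context_frequencies(reference: str) -> dict[str, int]:
    n = len(reference)
    freq: dict[str, int] = {}
    for i in range(n):
        ctx = reference[(i - 1) % n] + reference[i] + reference[(i + 1) % n]
        freq[ctx] = freq.get(ctx, 0) + 1
    return freq


def trinucleotide_spectrum(variants: pd.DataFrame, reference: str) -> tuple[pd.DataFrame, int]:
    """Strand-resolved trinucleotide substitution spectrum.

    For each substitution the immediate 5' and 3' bases are read off the
    circular reference; counts are normalised by the frequency of the context
    on each strand (the given sequence is the L strand, its reverse
    complement the H strand). Indels are skipped and counted. Returns
    ``(spectrum, n_skipped)``; de-normalising (rate x context frequency) and
    summing recovers the substitution total on each strand.
    """
    if len(reference) < 3:
        raise ValueError("reference must be at least 3 bases long")
    freq_l = _context_frequencies(reference)
    freq_h = _context_frequencies(_revcomp(reference))
    rows = []
    skipped = 0
    for _, v in variants.iterrows():
        ref, alt = str(v["ref"]), str(v["alt"])
        if len(ref) != 1 or len(alt) != 1:
            skipped += 1
            continue
        pos = int(v["position"])
        ctx_l = _context(reference, pos)
        sub_l = f"{ref}>{alt}"
        ctx_h = _revcomp(ctx_l)
        sub_h = f"{_revcomp(ref)}>{_revcomp(alt)}"
        rows.append(("L", ctx_l, sub_l))
        rows.append(("H", ctx_h, sub_h))
    if not rows:
        spectrum = pd.DataFrame(columns=["strand", "context", "substitution", "count", "context_freq", "rate"])
        return spectrum, skipped
    df = pd.DataFrame(rows, columns=["strand", "context", "substitution"])
    spectrum = df.value_counts(["strand", "context", "substitution"]).rename("count").reset_index()
    spectrum["context_freq"] = [
        (freq_l if s == "L" else freq_h).get(c, 0) for s, c in zip(spectrum["strand"], spectrum["context"])
    ]
    spectrum["rate"] = spectrum["count"] / spectrum["context_freq"].replace(0, np.nan)
    return spectrum.sort_values(["strand", "context", "substitution"]).reset_index(drop=True), skipped


def length_heteroplasmy(
    allele_counts: pd.DataFrame, ref_allele: str, min_total: int = 10
) -> pd.DataFrame:
    """Reference-allele heteroplasmy at a homopolymer length-polymorphic anchor.

    ``allele_counts`` is long format (``cell_id``, ``allele``, ``count``).
    Cells with fewer than ``min_total`` reads at the anchor are excluded
    (mirroring a minimum anchor coverage of 10 reads). Returns one row per
    included cell: reference heteroplasmy (ref reads / total reads) and the
    cell's major allele (ties favour the reference, then the shorter allele).
    """
    if (allele_counts["count"] < 0).any():
        raise ValueError("negative allele counts")
    rows = []
    for cell, grp in allele_counts.groupby("cell_id", sort=True):
        total = int(grp["count"].sum())
        if total < min_total:
            continue
        ref_n = int(grp.loc[grp["allele"] == ref_allele, "count"].sum())
        major = min(
            grp.to_dict("records"),
            key=lambda r: (-r["count"], r["allele"] != ref_allele, len(r["allele"]), r["allele"]),
        )["allele"]
        rows.append(
            {
                "cell_id": cell,
                "total": total,
                "ref_heteroplasmy": ref_n / total,
                "major_allele": major,
            }
        )
    out = pd.DataFrame(rows, columns=["cell_id", "total", "ref_heteroplasmy", "major_allele"])
    out.attrs["reason"] = "" if len(out) else "all_cells_below_min_total"
    return out


def write_vcf(records: list[VariantRecord], path, contig: str = "chrM", reference_length: int = MT_GENOME_LENGTH) -> None:
    """Write variant filter outcomes as VCF 4.2."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig},length={reference_length}>\n")
        for name in FILTER_NAMES:
            fh.write(f'##FILTER=<ID={name},Description="Failed {name} filter">\n')
        fh.write('##INFO=<ID=NCELLS,Number=1,Type=Integer,Description="Cells with alternate reads">\n')
        fh.write('##INFO=<ID=HET,Number=1,Type=Float,Description="Pooled heteroplasmy">\n')
        fh.write('##INFO=<ID=STRAND_R,Number=1,Type=Float,Description="Forward/reverse heteroplasmy Pearson R">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for rec in sorted(records, key=lambda r: (r.position, r.alt)):
            if rec.is_pass:
                filt = "PASS"
            else:
                filt = ";".join(n for n in FILTER_NAMES if n not in rec.filters_passed)
            info = f"NCELLS={rec.n_cells_detected};HET={rec.pooled_heteroplasmy:.6g}"
            if np.isfinite(rec.strand_r):
                info += f";STRAND_R={rec.strand_r:.6g}"
            fh.write(f"{contig}\t{rec.position}\t.\t{rec.ref}\t{rec.alt}\t.\t{filt}\t{info}\n")


def pearson_r(x, y) -> float:
    """Plain Pearson correlation (thin wrapper used by tests and reports)."""
    return float(stats.pearsonr(np.asarray(x, float), np.asarray(y, float))[0])
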