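"""Synthetic single-cell whole-genome datasets with coupled mtDNA/nuDNA structure.

The generator emulates amplification-free scWGS (DLP+-like) libraries: clones
with distinct mtDNA-to-nuDNA ratios (MNR), whole-genome-doubled (tetraploid)
subpopulations, clone-specific heteroplasmy profiles, right-skewed per-cell
mtDNA copy number dispersion, cell-size coupling, and binomially sampled
strand-split read counts at each variant site. It is the ground-truth source
for every downstream stage of the package.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

MT_GENOME_LENGTH = 16_569
#: Homopolymer repeat regions excluded from variant calling (1-based, inclusive).
BLACKLIST_REGIONS: tuple[tuple[int, int], ...] = ((513, 525), (3105, 3109))

_BASES = np.array(list("ACGT"))


class SimulationConfigError(ValueError):
    """Raised when a simulation configuration field is invalid."""


@dataclass
class SimulationConfig:
    """Parameters of one synthetic study.

    Defaults describe a two-clone, two-library experiment at the depth of a
    deeply sequenced lymphoblastoid library (~80x mean mtDNA site coverage,
    per-cell copy-number coefficient of variation 0.65, diploid MNR in the
    hundreds so that diploid cells carry several hundred mtDNA copies).
    """

    n_libraries: int = 2
    cells_per_library: int = 100
    n_clones: int = 2
    clone_fractions: tuple[float, ...] | None = None
    #: Expected mtDNA copies per average haploid nuclear genome, per clone.
    clone_mnr: tuple[float, ...] | None = None
    #: Probability that a cell of each clone is whole-genome doubled.
    wgd_fraction: tuple[float, ...] | float = 0.0
    #: Target coefficient of variation of true per-cell mtDNA copy number.
    cn_cv: float = 0.65
    n_variants: int = 10
    #: clones x variants matrix of true heteroplasmy; generated if omitted.
    clone_heteroplasmy: np.ndarray | None = None
    #: Mean reads per cell per mtDNA variant site (for a cell at the library-average copy number).
    mean_site_coverage: float = 80.0
    #: Mean per-cell nuclear read depth (mean per-base coverage).
    nu_depth_mean: float = 0.2
    #: mtDNA copies per micron of cell diameter (size coupling).
    diameter_slope: float = 24.0
    diameter_base_um: float = 15.0
    diameter_noise_sd_um: float = 1.5
    #: Number of 500-kb-equivalent nuclear bins.
    genome_bins: int = 200
    #: Fraction of bins a (non-ancestral) clone's profile deviates from flat diploid.
    clone_bin_alteration_fraction: float = 0.25
    #: Per-bin probability of a +/-1 state flip in an individual cell.
    bin_noise_rate: float = 0.02
    #: Fraction of cells given quality below the 0.75 gate.
    low_quality_fraction: float = 0.05
    #: Plant ~10% of variants inside the blacklist regions (filter exercise).
    blacklist_insertion: bool = False
    mt_genome_length: int = MT_GENOME_LENGTH
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_libraries", "cells_per_library", "n_clones", "n_variants", "genome_bins"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise SimulationConfigError(f"{name} must be a count >= 1, got {v!r}")
        if self.clone_fractions is None:
            self.clone_fractions = tuple([1.0 / self.n_clones] * self.n_clones)
        fr = np.asarray(self.clone_fractions, dtype=float)
        if fr.size != self.n_clones or abs(fr.sum() - 1.0) > 1e-9 or (fr < 0).any():
            raise SimulationConfigError(
                f"clone_fractions must be a length-{self.n_clones} probability vector summing to 1, got {self.clone_fractions!r}"
            )
        if self.clone_mnr is None:
            # geometric spacing around the scale of a diploid cell with ~750 copies
            self.clone_mnr = tuple(378.0 * (1.3**k) for k in range(self.n_clones))
        mnr = np.asarray(self.clone_mnr, dtype=float)
        if mnr.size != self.n_clones or (mnr <= 0).any():
            raise SimulationConfigError(f"clone_mnr must be {self.n_clones} positive reals, got {self.clone_mnr!r}")
        if np.isscalar(self.wgd_fraction):
            self.wgd_fraction = tuple([float(self.wgd_fraction)] * self.n_clones)
        wgd = np.asarray(self.wgd_fraction, dtype=float)
        if wgd.size != self.n_clones or (wgd < 0).any() or (wgd > 1).any():
            raise SimulationConfigError(f"wgd_fraction must be {self.n_clones} probabilities, got {self.wgd_fraction!r}")
        if self.cn_cv < 0:
            raise SimulationConfigError(f"cn_cv must be nonnegative, got {self.cn_cv!r}")
        if self.clone_heteroplasmy is not None:
            H = np.asarray(self.clone_heteroplasmy, dtype=float)
            if H.shape != (self.n_clones, self.n_variants):
                raise SimulationConfigError(
                    f"clone_heteroplasmy must have shape ({self.n_clones}, {self.n_variants}), got {H.shape}"
                )
            if (H < 0).any() or (H > 1).any():
                raise SimulationConfigError("clone_heteroplasmy entries must lie in [0, 1]")
            self.clone_heteroplasmy = H
        for name in ("mean_site_coverage", "nu_depth_mean"):
            if getattr(self, name) <= 0:
                raise SimulationConfigError(f"{name} must be positive, got {getattr(self, name)!r}")
        if not 0 <= self.low_quality_fraction <= 1:
            raise SimulationConfigError(f"low_quality_fraction must lie in [0, 1], got {self.low_quality_fraction!r}")
        if not 0 <= self.bin_noise_rate <= 1:
            raise SimulationConfigError(f"bin_noise_rate must lie in [0, 1], got {self.bin_noise_rate!r}")


@dataclass
class GroundTruth:
    """True generative state of a simulated dataset.

    ``cells`` has one row per cell (clone, ploidy label, true copy number);
    ``variants`` one row per site (position, alleles, functional class);
    ``clone_heteroplasmy`` is the clones x variants truth matrix. A cell's
    true heteroplasmy vector is its clone's row of that matrix.
    """

    cells: pd.DataFrame
    variants: pd.DataFrame
    clone_heteroplasmy: np.ndarray
    reference: str
    clone_labels: tuple[str, ...] = field(default_factory=tuple)

    def cell_heteroplasmy(self) -> np.ndarray:
        """cells x variants matrix of true (pre-sampling) heteroplasmy."""
        return self.clone_heteroplasmy[self.cells["true_clone"].to_numpy()]


def _lognormal_sigma(cv: float) -> float:
    """Lognormal shape parameter giving coefficient of variation ``cv``."""
    return float(np.sqrt(np.log1p(cv**2)))


def _default_heteroplasmy(rng: np.random.Generator, k: int, v: int) -> np.ndarray:
    """Clone-discriminating default profile: each variant is carried by one clone."""
    H = np.zeros((k, v))
    owners = np.arange(v) % k
    H[owners, np.arange(v)] = rng.uniform(0.4, 0.9, size=v)
    return H


def _variant_positions(rng: np.random.Generator, cfg: SimulationConfig) -> np.ndarray:
    length = cfg.mt_genome_length
    bad = np.zeros(length + 1, dtype=bool)
    for lo, hi in BLACKLIST_REGIONS:
        if hi <= length:
            bad[lo : hi + 1] = True
    allowed = np.flatnonzero(~bad[1:]) + 1
    n_black = 0
    if cfg.blacklist_insertion:
        n_black = max(1, int(round(0.1 * cfg.n_variants)))
        n_black = min(n_black, cfg.n_variants)
    clean = rng.choice(allowed, size=cfg.n_variants - n_black, replace=False)
    if n_black:
        black_pool = np.flatnonzero(bad[1:]) + 1
        black = rng.choice(black_pool, size=n_black, replace=False)
        pos = np.concatenate([clean, black])
    else:
        pos = clean
    return np.sort(pos)


_VARIANT_CLASSES = ("truncating", "silent", "missense", "noncoding")


def simulate_dataset(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw one synthetic dataset.

    Returns ``(cells, counts, truth)`` where ``cells`` has one row per cell
    (depths, quality, binned nuclear states, diameter), ``counts`` is the
    long-format per-(cell, variant) strand-split allele count table, and
    ``truth`` records the generative state. Deterministic given
    ``config.seed``.

    Generative model per cell: clone ~ Categorical(clone_fractions); the cell
    is tetraploid with its clone's WGD probability, implemented as exact
    doubling of the clone's diploid bin-state vector; true mtDNA copy number
    is clone MNR x average ploidy x lognormal noise calibrated to ``cn_cv``
    (so MNR is ploidy-homeostatic by construction); per-site read totals are
    Poisson with rate proportional to the cell's copy number relative to its
    library mean; alternate reads are Binomial(total, clone heteroplasmy) and
    each read lands on the forward strand with probability 1/2.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    K, V = cfg.n_clones, cfg.n_variants
    n_cells = cfg.n_libraries * cfg.cells_per_library

    reference = "".join(rng.choice(_BASES, size=cfg.mt_genome_length))
    positions = _variant_positions(rng, cfg)
    ref_alleles = np.array([reference[p - 1] for p in positions])
    alt_alleles = np.array(
        [rng.choice([b for b in "ACGT" if b != r]) for r in ref_alleles]
    )
    var_class = rng.choice(_VARIANT_CLASSES, size=V, p=(0.15, 0.2, 0.35, 0.3))

    if cfg.clone_heteroplasmy is None:
        H = _default_heteroplasmy(rng, K, V)
    else:
        H = np.asarray(cfg.clone_heteroplasmy, dtype=float)

    # clone nuclear profiles: each clone gets its own bin alterations so clones
    # are mutually distinguishable in correlation space; a single-clone
    # simulation stays flat diploid
    profiles = np.full((K, cfg.genome_bins), 2, dtype=int)
    for k in range(K) if K > 1 else []:
        n_alt = int(round(cfg.clone_bin_alteration_fraction * cfg.genome_bins))
        which = rng.choice(cfg.genome_bins, size=n_alt, replace=False)
        profiles[k, which] += rng.choice([-1, 1], size=n_alt)
    clone_labels = tuple(string.ascii_uppercase[k] for k in range(K))

    clone = rng.choice(K, size=n_cells, p=np.asarray(cfg.clone_fractions, dtype=float))
    wgd_p = np.asarray(cfg.wgd_fraction, dtype=float)[clone]
    is_tetra = rng.random(n_cells) < wgd_p

    bin_states = profiles[clone].copy()
    bin_states[is_tetra] *= 2
    flip = rng.random(bin_states.shape) < cfg.bin_noise_rate
    delta = rng.choice([-1, 1], size=bin_states.shape)
    bin_states = np.where(flip, np.maximum(bin_states + delta, 0), bin_states)

    avg_ploidy = bin_states.mean(axis=1)
    # median-centred lognormal: clone_mnr is the clone's median MNR, matching
    # the median-based summaries used downstream
    sigma = _lognormal_sigma(cfg.cn_cv)
    if sigma > 0:
        noise = rng.lognormal(mean=0.0, sigma=sigma, size=n_cells)
    else:
        noise = np.ones(n_cells)
    mnr_clone = np.asarray(cfg.clone_mnr, dtype=float)
    true_cn = mnr_clone[clone] * avg_ploidy * noise
    true_mnr = true_cn / avg_ploidy

    nu_depth = rng.gamma(shape=20.0, scale=cfg.nu_depth_mean / 20.0, size=n_cells)
    mt_depth = nu_depth * true_mnr

    n_low = rng.binomial(n_cells, cfg.low_quality_fraction)
    quality = rng.uniform(0.75, 1.0, size=n_cells)
    if n_low:
        low_idx = rng.choice(n_cells, size=n_low, replace=False)
        quality[low_idx] = rng.uniform(0.2, 0.75, size=n_low)

    diameter = (
        cfg.diameter_base_um
        + true_cn / cfg.diameter_slope
        + rng.normal(0.0, cfg.diameter_noise_sd_um, size=n_cells)
    )

    library = np.repeat(np.arange(cfg.n_libraries), cfg.cells_per_library)
    cell_id = np.array([f"cell{c:05d}" for c in range(n_cells)])
    library_id = np.array([f"LIB{l:02d}" for l in library])

    cells = pd.DataFrame(
        {
            "cell_id": cell_id,
            "library_id": library_id,
            "sample_id": "SIM01",
            "quality": quality,
            "mt_depth": mt_depth,
            "nu_depth": nu_depth,
            "diameter_um": diameter,
            "bin_states": [",".join(map(str, row)) for row in bin_states],
        }
    )

    # per-library mean true copy number sets the coverage scale
    lib_mean = np.zeros(n_cells)
    for l in range(cfg.n_libraries):
        mask = library == l
        lib_mean[mask] = true_cn[mask].mean()
    site_rate = cfg.mean_site_coverage * true_cn / lib_mean  # (cells,)

    total = rng.poisson(np.repeat(site_rate, V)).reshape(n_cells, V)
    h_cell = H[clone]  # (cells, variants)
    alt = rng.binomial(total, h_cell)
    fwd_alt = rng.binomial(alt, 0.5)
    fwd_ref = rng.binomial(total - alt, 0.5)
    fwd_total = fwd_alt + fwd_ref
    rev_alt = alt - fwd_alt
    rev_total = total - fwd_total

    counts = pd.DataFrame(
        {
            "cell_id": np.repeat(cell_id, V),
            "position": np.tile(positions, n_cells),
            "ref": np.tile(ref_alleles, n_cells),
            "alt": np.tile(alt_alleles, n_cells),
            "fwd_alt": fwd_alt.ravel(),
            "rev_alt": rev_alt.ravel(),
            "fwd_total": fwd_total.ravel(),
            "rev_total": rev_total.ravel(),
        }
    )

    truth_cells = pd.DataFrame(
        {
            "cell_id": cell_id,
            "true_clone": clone,
            "true_clone_label": [clone_labels[k] for k in clone],
            "true_ploidy_label": np.where(is_tetra, "tetraploid", "diploid"),
            "true_cn": true_cn,
            "true_mnr": true_mnr,
        }
    )
    truth_variants = pd.DataFrame(
        {
            "position": positions,
            "ref": ref_alleles,
            "alt": alt_alleles,
            "var_class": var_class,
        }
    )
    truth = GroundTruth(
        cells=truth_cells,
        variants=truth_variants,
        clone_heteroplasmy=H,
        reference=reference,
        clone_labels=clone_labels,
    )
    return cells, counts, truth


def inject_strand_artifact(counts: pd.DataFrame, position: int, n_reads: int = 20) -> pd.DataFrame:
    """Force forward-only alternate support at ``position`` (negative control).

    Every row at the position gets ``n_reads`` forward alternate reads and
    zero reverse alternate reads — the signature of a strand artifact that the
    strand-support/concordance filters must reject.
    """
    out = counts.copy()
    at = out["position"] == position
    out.loc[at, "fwd_alt"] = n_reads
    out.loc[at, "fwd_total"] = np.maximum(out.loc[at, "fwd_total"], n_reads)
    out.loc[at, "rev_alt"] = 0
    return out


def _write_fasta(path: Path, name: str, seq: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name} circular\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i : i + width] + "\n")


def _read_fasta(path: Path) -> str:
    seq: list[str] = []
    with open(path) as fh:
        for line in fh:
            if not line.startswith(">"):
                seq.append(line.strip())
    return "".join(seq)


def write_dataset(
    cells: pd.DataFrame, counts: pd.DataFrame, truth: GroundTruth, out_dir: str | Path
) -> dict:
    """Write the on-disk dataset and return its manifest.

    Emits ``cells.tsv``, ``counts.tsv``, ``truth_cells.tsv``,
    ``truth_variants.tsv``, ``truth_clone_heteroplasmy.tsv``, ``reference.fa``
    and ``manifest.json``. Integer fields round-trip exactly; floats at full
    ``repr`` precision.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cells.to_csv(out / "cells.tsv", sep="\t", index=False)
    counts.to_csv(out / "counts.tsv", sep="\t", index=False)
    truth.cells.to_csv(out / "truth_cells.tsv", sep="\t", index=False)
    truth.variants.to_csv(out / "truth_variants.tsv", sep="\t", index=False)
    pd.DataFrame(
        truth.clone_heteroplasmy,
        index=list(truth.clone_labels) or range(truth.clone_heteroplasmy.shape[0]),
        columns=[str(p) for p in truth.variants["position"]],
    ).to_csv(out / "truth_clone_heteroplasmy.tsv", sep="\t", index_label="clone")
    _write_fasta(out / "reference.fa", "chrM", truth.reference)
    manifest = {
        "files": {
            "cells.tsv": {"rows": int(len(cells))},
            "counts.tsv": {"rows": int(len(counts))},
            "truth_cells.tsv": {"rows": int(len(truth.cells))},
            "truth_variants.tsv": {"rows": int(len(truth.variants))},
            "reference.fa": {"length": len(truth.reference)},
        },
        "n_cells": int(len(cells)),
        "n_variants": int(len(truth.variants)),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


_CELL_DTYPES = {"cell_id": str, "library_id": str, "sample_id": str}
_COUNT_INT_COLS = ["position", "fwd_alt", "rev_alt", "fwd_total", "rev_total"]


def read_dataset(in_dir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Read a dataset written by :func:`write_dataset`."""
    d = Path(in_dir)
    cells = pd.read_csv(d / "cells.tsv", sep="\t", dtype=_CELL_DTYPES)
    if cells.empty:
        cells = cells.astype({"bin_states": str}, errors="ignore")
    counts = pd.read_csv(d / "counts.tsv", sep="\t", dtype={"cell_id": str, "ref": str, "alt": str})
    for col in _COUNT_INT_COLS:
        if col in counts.columns:
            counts[col] = counts[col].astype(np.int64)
    truth_cells = pd.read_csv(d / "truth_cells.tsv", sep="\t", dtype={"cell_id": str})
    truth_variants = pd.read_csv(d / "truth_variants.tsv", sep="\t", dtype={"ref": str, "alt": str})
    H = pd.read_csv(d / "truth_clone_heteroplasmy.tsv", sep="\t", index_col="clone")
    reference = _read_fasta(d / "reference.fa")
    truth = GroundTruth(
        cells=truth_cells,
        variants=truth_variants,
        clone_heteroplasmy=H.to_numpy(dtype=float),
        reference=reference,
        clone_labels=tuple(str(i) for i in H.index),
    )
    return cells, counts, truth


def parse_bin_states(cells: pd.DataFrame) -> np.ndarray:
    """Decode the comma-joined ``bin_states`` column to an int matrix."""
    return np.array([[int(x) for x in s.split(",")] for s in cells["bin_states"]])


def config_to_dict(cfg: SimulationConfig) -> dict:
    d = asdict(cfg)
    if d.get("clone_heteroplasmy") is not None:
        d["clone_heteroplasmy"] = np.asarray(d["clone_heteroplasmy"]).tolist()
    return d
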