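"""End-to-end orchestration: simulate -> quality gate -> genotyping ->
copy number -> clone inference (mtDNA and nuclear) -> association.

`run_pipeline` drives the whole analysis from a single `RunConfig` whose
defaults are the analysis defaults throughout the package (quality gate
0.75, strand support 2+2, strand correlation R >= 0.2, blacklist 513-525 /
3105-3109, learning rate 0.1, ELBO relative tolerance 1e-5, min 10 alternate
reads, heteroplasmy window (0.05, 0.95), range 0.15). All randomness flows
from one master seed via named substreams per stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from mitodlp import __version__, assoc, clones_nu, copynum, genotyping, mitybayes
from mitodlp.simulate import SimulationConfig, config_to_dict, parse_bin_states, read_dataset, simulate_dataset, write_dataset

log = logging.getLogger("mitodlp")

_STAGES = ("simulate", "genotype", "copynum", "clones", "assoc")


class RunConfigError(ValueError):
    """Invalid run configuration (raised before any compute)."""


@dataclass
class RunConfig:
    """Full pipeline configuration; defaults are the canonical analysis."""

    outdir: str = "run"
    seed: int = 0
    simulate: bool = True
    input_dir: str | None = None
    sim: dict = field(default_factory=dict)
    # quality gate / genotyping
    min_quality: float = 0.75
    min_strand_reads: int = 2
    min_strand_r: float = 0.2
    min_strand_cells: int = 3
    # clone model
    mitybayes_k: int | None = None
    lr: float = 0.1
    rel_tol: float = 1e-5
    n_restarts: int = 4
    min_prob: float = 0.9
    backend: str = "em"
    # association
    min_alt: int = 10
    het_lo: float = 0.05
    het_hi: float = 0.95
    min_range: float = 0.15
    # nuclear clones
    nu_n_clones: int | None = None
    nu_method: str = "fallback"
    resume: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_quality <= 1.0:
            raise RunConfigError(f"min_quality must lie in [0, 1], got {self.min_quality}")
        if not 0.0 <= self.het_lo < self.het_hi <= 1.0:
            raise RunConfigError("require 0 <= het_lo < het_hi <= 1")
        if self.min_strand_reads < 0 or self.min_alt < 0:
            raise RunConfigError("read-count thresholds must be nonnegative")
        if self.rel_tol <= 0 or self.lr <= 0:
            raise RunConfigError("lr and rel_tol must be positive")
        if not self.simulate and self.input_dir is None:
            raise RunConfigError("either simulate=True or input_dir must be given")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _stage_seed(master: int, stage: str) -> int:
    """Named substream: stable per-stage seed derived from the master seed."""
    h = np.random.SeedSequence([master, sum(ord(c) for c in stage)])
    return int(h.generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis; returns the run directory.

    Stages are idempotent: with ``resume=True`` a stage whose outputs exist
    is skipped. On stage failure the exception names the stage and partial
    outputs are retained.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.to_yaml(out / "config.yaml")
    counts_report: dict = {"package_version": __version__, "seed": config.seed}

    stage = "simulate"
    try:
        ds_dir = out / "dataset"
        if config.simulate:
            if config.resume and (ds_dir / "manifest.json").exists():
                cells, counts, truth = read_dataset(ds_dir)
            else:
                sim_cfg = SimulationConfig(**{"seed": _stage_seed(config.seed, stage), **config.sim})
                cells, counts, truth = simulate_dataset(sim_cfg)
                write_dataset(cells, counts, truth, ds_dir)
                counts_report["sim_config"] = config_to_dict(sim_cfg)
        else:
            cells, counts, truth = read_dataset(config.input_dir)
        counts_report["n_cells_total"] = int(len(cells))

        stage = "genotype"
        gated, gate_counts = copynum.quality_gate(cells, config.min_quality)
        counts_report["quality_gate"] = gate_counts
        gcounts = counts[counts["cell_id"].isin(gated["cell_id"])]
        records = genotyping.apply_filter_stack(
            gcounts,
            min_strand_reads=config.min_strand_reads,
            min_r=config.min_strand_r,
            min_cells=config.min_strand_cells,
            reference_length=len(truth.reference) if truth.reference else 16_569,
            variant_classes=truth.variants if "var_class" in truth.variants.columns else None,
        )
        genotyping.write_vcf(records, out / "variants.vcf", reference_length=len(truth.reference))
        pass_pos = [r.position for r in records if r.is_pass]
        het, depth = genotyping.genotype_cells(gcounts, pass_pos)
        het.to_csv(out / "heteroplasmy.tsv", sep="\t", float_format="%.6g")
        depth.to_csv(out / "depth.tsv", sep="\t")
        counts_report["n_variants"] = len(records)
        counts_report["n_pass_variants"] = len(pass_pos)

        stage = "copynum"
        percell = copynum.percell_table(gated)
        keep_cols = [
            "cell_id", "library_id", "sample_id", "average_ploidy", "baseline_ploidy",
            "wgd_label", "mnr", "cn", "diameter_um",
        ]
        percell[keep_cols].to_csv(out / "percell_cn.tsv", sep="\t", index=False, float_format="%.6g")
        contrast = copynum.ploidy_contrast(percell)
        contrast.to_csv(out / "ploidy_contrast.tsv", sep="\t", index=False, float_format="%.6g")
        counts_report["wgd_labels"] = percell["wgd_label"].value_counts().to_dict()

        stage = "clones"
        sub = gcounts[gcounts["position"].isin(pass_pos)]
        altm = (
            sub.assign(alt=sub["fwd_alt"] + sub["rev_alt"])
            .pivot_table(index="cell_id", columns="position", values="alt", aggfunc="sum", fill_value=0)
        )
        totm = (
            sub.assign(total=sub["fwd_total"] + sub["rev_total"])
            .pivot_table(index="cell_id", columns="position", values="total", aggfunc="sum", fill_value=0)
        )
        model = None
        if len(altm.columns) and len(altm) >= 2:
            K = config.mitybayes_k
            if K is None:
                K, _ = mitybayes.select_k(
                    altm.to_numpy(), totm.to_numpy(), K_grid=range(1, 6),
                    seed=_stage_seed(config.seed, "mitybayes"),
                    n_restarts=config.n_restarts, backend=config.backend,
                )
            model = mitybayes.fit(
                altm.to_numpy(), totm.to_numpy(), K,
                priors=mitybayes.Priors(), backend=config.backend, lr=config.lr,
                rel_tol=config.rel_tol, n_restarts=config.n_restarts,
                seed=_stage_seed(config.seed, "mitybayes"),
            )
            labels = mitybayes.assign_clones(model, config.min_prob)
            pd.DataFrame(
                {
                    "cell_id": altm.index,
                    "clone": [str(l) for l in labels],
                    "max_prob": model.gamma.max(axis=1),
                }
            ).to_csv(out / "clones.tsv", sep="\t", index=False, float_format="%.6g")
            with open(out / "model.json", "w") as fh:
                json.dump(
                    {
                        "K": model.K,
                        "pi": np.round(model.pi, 8).tolist(),
                        "P": np.round(model.P, 8).tolist(),
                        "contribution": np.round(model.contribution, 8).tolist(),
                        "elbo_trace": np.round(model.elbo_trace, 6).tolist(),
                        "converged": model.converged,
                        "backend": model.backend,
                        "seed": model.seed,
                        "package_version": __version__,
                    },
                    fh,
                    indent=2,
                )
            counts_report["mitybayes_k"] = model.K
        bins = pd.DataFrame(parse_bin_states(gated), index=gated["cell_id"])
        nu = clones_nu.cluster_cells_nu(
            bins, n_clones=config.nu_n_clones, method=config.nu_method,
            seed=_stage_seed(config.seed, "clones_nu"),
        )
        pd.DataFrame(
            {"cell_id": nu.labels.index, "clone": nu.labels.values, "method": nu.method}
        ).to_csv(out / "nuclones.tsv", sep="\t", index=False)
        if model is not None:
            mt_labels = pd.Series(
                [str(l) for l in mitybayes.assign_clones(model, config.min_prob)], index=altm.index
            )
            check = clones_nu.crosscheck_clones(nu.labels, mt_labels)
            with open(out / "crosscheck.json", "w") as fh:
                json.dump(
                    {
                        "ari": check["ari"],
                        "n_shared": check["n_shared"],
                        "modal_mt_clone": check["modal_mt_clone"],
                        "contingency": check["contingency"].to_dict(),
                    },
                    fh,
                    indent=2,
                    default=str,
                )
            counts_report["nu_mt_ari"] = check["ari"]

        stage = "assoc"
        indexed = percell.set_index("cell_id")
        common = het.index.intersection(indexed.index)
        obs = assoc.concordance_filters(
            het.loc[common],
            altm.reindex(index=common, columns=het.columns, fill_value=0),
            cn=indexed.loc[common, "cn"],
            strata=indexed.loc[common, "library_id"],
            min_alt=config.min_alt,
            lo=config.het_lo,
            hi=config.het_hi,
            min_range=config.min_range,
        )
        ctable = assoc.concordance_table(obs)
        ctable.to_csv(out / "assoc.tsv", sep="\t", index=False, float_format="%.6g")
        reg = assoc.size_regression(percell)
        reg.to_csv(out / "regression.tsv", sep="\t", index=False, float_format="%.6g")
        counts_report["n_assoc_variants"] = int(len(ctable))
    except Exception:
        log.exception("pipeline stage %r failed", stage)
        with open(out / "error.log", "w") as fh:
            fh.write(f"stage {stage} failed\n")
        raise

    _write_report(out, counts_report)
    with open(out / "run_summary.json", "w") as fh:
        json.dump(counts_report, fh, indent=2, default=str)
    return out


def _write_report(out: Path, rep: dict) -> None:
    lines = [
        "# Run report",
        "",
        f"- package version: {rep.get('package_version')}",
        f"- master seed: {rep.get('seed')}",
        f"- cells (total / after quality gate): {rep.get('n_cells_total')} / {rep.get('quality_gate', {}).get('kept')}",
        f"- variants (called / PASS): {rep.get('n_variants')} / {rep.get('n_pass_variants')}",
        f"- baseline-ploidy labels: {rep.get('wgd_labels')}",
        f"- clone model K: {rep.get('mitybayes_k', 'n/a')}",
        f"- nuclear/mtDNA clone agreement (ARI): {rep.get('nu_mt_ari', 'n/a')}",
        f"- variants entering the concordance test: {rep.get('n_assoc_variants')}",
        "",
    ]
    (out / "report.md").write_text("\n".join(lines))
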