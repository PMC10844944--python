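"""End-to-end study orchestration.

Runs, for every protein-outcome pair: per-study cis extraction and QC ->
fixed-effects meta-analysis with heterogeneity filtering -> instrument
construction (significance filter, greedy LD pruning, strength statistics)
-> MR estimation (Wald ratio or correlated IVW) with leave-one-out ->
pairwise-conditional colocalisation around the sentinel SNP -> per-arm
BH-FDR tiering -> optional replication pooling and missense flagging.
Failures are per-pair: a degenerate instrument yields a status row, not an
aborted study.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coloc, evidence, instruments, meta, mr, simulate, summary_io

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    proteins: dict  # protein_id -> {studies: {study_id: path}, panel: {...},
    #                 gene_id, n_exposure}
    outcomes: dict  # outcome_id -> path
    gene_regions: str
    output_dir: str
    annotations: str | None = None
    scores: str | None = None
    replication: dict = field(default_factory=dict)  # outcome_id -> path
    seed: int = 0
    cis_window: int = 250_000
    maf_min: float = 0.01
    palindrome_maf_limit: float = 0.40
    p_sig: float = 5e-8
    p_het_threshold: float = 0.001
    prune_r2: float = 0.10
    pph4_threshold: float = 0.70
    score_threshold: float = 0.05
    missense_r2: float = 0.80
    coloc_priors: tuple = (1e-4, 1e-4, 1e-5)
    moloc_priors: tuple = (1e-4, 1e-6, 1e-7)

    def validate(self) -> None:
        for name, lo, hi in [
            ("maf_min", 0, 0.5),
            ("palindrome_maf_limit", 0, 0.5),
            ("p_sig", 0, 1),
            ("p_het_threshold", 0, 1),
            ("prune_r2", 0, 1),
            ("pph4_threshold", 0, 1),
            ("score_threshold", 0, 1),
            ("missense_r2", 0, 1),
        ]:
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"config {name}={v} outside [{lo}, {hi}]")
        if self.cis_window < 0:
            raise ValueError("cis_window must be non-negative")
        for pid, pconf in self.proteins.items():
            for sid, path in pconf["studies"].items():
                if not Path(path).exists():
                    raise FileNotFoundError(f"{pid}/{sid}: {path}")
            for path in pconf["panel"].values():
                if not Path(path).exists():
                    raise FileNotFoundError(f"{pid} panel: {path}")
        for oid, path in self.outcomes.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"outcome {oid}: {path}")
        if not Path(self.gene_regions).exists():
            raise FileNotFoundError(f"gene regions: {self.gene_regions}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in raw.items() if k in known})

    def config_hash(self) -> str:
        blob = json.dumps(
            {k: getattr(self, k) for k in sorted(self.__dataclass_fields__)},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _align_to_reference(ref: pd.DataFrame, other: pd.DataFrame) -> pd.DataFrame:
    """Re-express ``other`` on the reference study's allele coding."""
    h = summary_io.harmonise(ref, other)
    return pd.DataFrame(
        {
            "chrom": h["chrom"], "pos": h["pos"], "rsid": h["rsid"],
            "ea": h["ea"], "oa": h["oa"], "eaf": h["eaf_out"],
            "beta": h["beta_out"], "se": h["se_out"],
            "pvalue": h["pvalue_out"], "n": h["n_out"],
        }
    )


def _meta_exposure(pconf: dict, region, cfg: PipelineConfig) -> pd.DataFrame:
    """Per-study cis extraction + QC, allele alignment, meta-analysis and
    heterogeneity filtering for one protein."""
    studies = {}
    for sid, path in pconf["studies"].items():
        df = summary_io.read_summary(path)
        df = instruments.select_cis(df, region, cfg.cis_window)
        # frequency filters are per-study, pre-meta; significance comes later
        df = instruments.apply_qc_filters(
            df, cfg.maf_min, cfg.palindrome_maf_limit, p_sig=1.1
        )
        studies[sid] = df
    sids = list(studies)
    ref = studies[sids[0]]
    aligned = {sids[0]: ref}
    for sid in sids[1:]:
        aligned[sid] = _align_to_reference(ref, studies[sid])
    pooled = meta.meta_analyse(aligned)
    pooled = meta.filter_heterogeneous(pooled, cfg.p_het_threshold)
    return pooled


def _coloc_for_pair(harmonised, ld, instrument, cfg):
    sentinel = instrument.sentinel
    lo = int(sentinel["pos"]) - cfg.cis_window
    hi = int(sentinel["pos"]) + cfg.cis_window
    win_df = harmonised.loc[
        (harmonised["pos"] >= lo) & (harmonised["pos"] <= hi)
    ].reset_index(drop=True)
    window = coloc.ColocWindow.from_harmonised(win_df)
    keys = [
        summary_io.variant_key(c, p)
        for c, p in zip(win_df["chrom"], win_df["pos"])
    ]
    return coloc.pwcoco(window, ld.submatrix(keys), cfg.coloc_priors, cfg.p_sig)


def run_pipeline(config: PipelineConfig) -> pd.DataFrame:
    """Execute the full study; returns the evidence table (also written to
    ``output_dir`` along with MR/coloc tables and a run manifest)."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    regions = instruments.read_gene_regions(config.gene_regions)
    annotations = (
        pd.read_csv(config.annotations, sep="\t")
        if config.annotations
        else None
    )
    scores = (
        pd.read_csv(config.scores, sep="\t")
        if config.scores
        else pd.DataFrame(columns=["protein_id", "outcome_id", "score"])
    )

    outcome_tables = {
        oid: summary_io.read_summary(path)
        for oid, path in config.outcomes.items()
    }
    replication_tables = {
        oid: summary_io.read_summary(path)
        for oid, path in config.replication.items()
    }

    rows = []
    for pid, pconf in config.proteins.items():
        region = regions[pconf.get("gene_id", pid)]
        panel = summary_io.read_panel(
            pconf["panel"]["haplotypes"], pconf["panel"]["variants"]
        )
        try:
            pooled = _meta_exposure(pconf, region, config)
        except Exception as exc:  # degenerate exposure: fail every pair
            logger.error("%s: exposure stage failed: %s", pid, exc)
            for oid in config.outcomes:
                rows.append({"protein_id": pid, "outcome_id": oid,
                             "status": f"failed:exposure:{exc}"})
            continue
        for oid, otab in outcome_tables.items():
            try:
                row = _run_pair(
                    pid, oid, pooled, otab, region, panel, config,
                    annotations, replication_tables.get(oid),
                    pconf.get("n_exposure"),
                )
            except Exception as exc:
                logger.error("%s-%s failed: %s", pid, oid, exc)
                row = {"protein_id": pid, "outcome_id": oid,
                       "status": f"failed:{exc}"}
            rows.append(row)

    table = pd.DataFrame(rows)
    for col in ("pvalue", "pph4"):
        if col not in table.columns:
            table[col] = np.nan
    ok = table["status"] == "estimated"

    # per-arm FDR over all attempted pairs in the arm
    pairs = list(zip(table["protein_id"], table["outcome_id"]))
    validation, _ = evidence.partition_arms(pairs, scores, config.score_threshold)
    vset = set(validation)
    table["arm"] = [
        "validation" if p in vset else "discovery" for p in pairs
    ]
    table["q_value"] = np.nan
    for arm in ("validation", "discovery"):
        mask = ok & (table["arm"] == arm)
        if mask.any():
            table.loc[mask, "q_value"] = evidence.bh_fdr(
                table.loc[mask, "pvalue"]
            )
    table["tier"] = [
        evidence.tier(q) if np.isfinite(q) else ""
        for q in table["q_value"]
    ]
    table["colocalised"] = table["pph4"] > config.pph4_threshold

    table = table.sort_values(["protein_id", "outcome_id"]).reset_index(drop=True)
    front = ["protein_id", "outcome_id", "arm", "status"]
    table = table[front + [c for c in table.columns if c not in front]]
    table.to_csv(outdir / "evidence.tsv", sep="\t", index=False,
                 float_format="%.8g")

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_pairs": len(table),
        "n_estimated": int(ok.sum()),
        "stage_counts": {
            "proteins": len(config.proteins),
            "outcomes": len(config.outcomes),
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return table


def _run_pair(pid, oid, pooled, outcome_table, region, panel, cfg,
              annotations, replication_table, n_exposure) -> dict:
    out_cis = instruments.select_cis(outcome_table, region, cfg.cis_window)
    harmonised = summary_io.harmonise(
        pooled, out_cis, cfg.palindrome_maf_limit
    )
    if len(harmonised) == 0:
        return {"protein_id": pid, "outcome_id": oid,
                "status": "failed:no-overlap"}
    ld = summary_io.compute_ld(panel, harmonised)

    sig = harmonised.loc[harmonised["pvalue_exp"] < cfg.p_sig]
    if len(sig) == 0:
        return {"protein_id": pid, "outcome_id": oid,
                "status": "failed:no-significant-cis-snp"}
    instrument = instruments.build_instrument(
        pid, sig, ld.submatrix(
            [summary_io.variant_key(c, p)
             for c, p in zip(sig["chrom"], sig["pos"])]
        ), cfg.prune_r2,
    )
    n_eff = float(n_exposure or sig["n_exp"].max())
    r2_total, f_stat = instruments.instrument_strength(instrument, n_eff)

    est = mr.estimate(instrument, oid)
    loo_flag = ""
    if instrument.k >= 3:
        loo = mr.leave_one_out(instrument, oid)
        loo_flag = ";".join(loo.influential)

    pw = _coloc_for_pair(harmonised, ld, instrument, cfg)

    row = {
        "protein_id": pid, "outcome_id": oid, "status": "estimated",
        "method": est.method, "k_snps": est.k_snps,
        "beta": est.beta, "se": est.se, "or_value": est.or_value,
        "ci_low": est.ci_low, "ci_high": est.ci_high, "pvalue": est.pvalue,
        "q_gls": est.q_gls, "phi": est.phi,
        "r2_total": r2_total, "f_stat": f_stat,
        "sentinel": summary_io.variant_key(
            instrument.sentinel["chrom"], instrument.sentinel["pos"]
        ),
        "pph0": pw.best.pph0, "pph1": pw.best.pph1, "pph2": pw.best.pph2,
        "pph3": pw.best.pph3, "pph4": pw.best.pph4,
        "coloc_context": pw.best.conditional_context,
        "n_coloc_variants": pw.best.n_variants,
        "loo_influential": loo_flag,
    }

    if annotations is not None and len(annotations):
        flags = evidence.flag_missense(
            instrument, annotations, ld, cfg.missense_r2, oid
        )
        row["missense_flag"] = any(flags.flags.values())
        if flags.revised is not None:
            row["or_revised"] = flags.revised.or_value

    if replication_table is not None:
        rep_cis = instruments.select_cis(replication_table, region, cfg.cis_window)
        rep_h = summary_io.harmonise(pooled, rep_cis, cfg.palindrome_maf_limit)
        rep_h["key"] = rep_h["chrom"].astype(str) + ":" + rep_h["pos"].astype(str)
        rep_h = rep_h.set_index("key")
        if all(k in rep_h.index for k in instrument.keys):
            rep_snps = instrument.snps.copy()
            rep_snps["beta_out"] = rep_h.loc[instrument.keys, "beta_out"].to_numpy()
            rep_snps["se_out"] = rep_h.loc[instrument.keys, "se_out"].to_numpy()
            rep_inst = instruments.Instrument(pid, rep_snps, instrument.ld)
            rep_est = mr.estimate(rep_inst, oid)
            pooled_est = evidence.replication_meta(est, rep_est)
            row.update(
                or_replication=rep_est.or_value,
                or_pooled_fixed=float(np.exp(pooled_est.beta_fixed)),
                or_pooled_random=float(np.exp(pooled_est.beta_random)),
                i2=pooled_est.i2, tau2=pooled_est.tau2,
            )
    return row


# ---------------------------------------------------------------------------
# synthetic studies


def write_synthetic_study(
    specs: dict[tuple[str, str], simulate.ScenarioSpec],
    outdir,
    seed: int = 0,
    **config_overrides,
) -> PipelineConfig:
    """Generate a full synthetic study on disk and its pipeline config.

    ``specs`` maps (protein_id, outcome_id) pairs to scenarios.  Each
    protein gets its own chromosome, panel and exposure studies (generated
    once, from its first pair's spec); each outcome file concatenates
    per-region stats across proteins.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    proteins = sorted({p for p, _ in specs})
    outcomes = sorted({o for _, o in specs})
    chrom_of = {p: str(i + 1) for i, p in enumerate(proteins)}

    pconfigs = {}
    regions = []
    exposure_truth = {}
    panels = {}
    for i, pid in enumerate(proteins):
        first = next(s for (p, _), s in specs.items() if p == pid)
        spec = simulate.replace_spec(
            first, chrom=chrom_of[pid], seed=seed + 1000 * i
        )
        panel = simulate.simulate_panel(spec)
        panels[pid] = (panel, spec)
        exposure_truth[pid] = spec.causal_snps_exposure
        hap_p = outdir / f"panel_{pid}.hap.tsv"
        var_p = outdir / f"panel_{pid}.var.tsv"
        summary_io.write_panel(panel, hap_p, var_p)
        study_paths = {}
        for sid, df in simulate.simulate_exposure_gwas(panel, spec).items():
            path = outdir / f"exposure_{pid}_{sid}.tsv"
            summary_io.write_summary(df, path)
            study_paths[sid] = str(path)
        pconfigs[pid] = {
            "studies": study_paths,
            "panel": {"haplotypes": str(hap_p), "variants": str(var_p)},
            "gene_id": pid,
            "n_exposure": spec.n_exposure,
        }
        g = spec.gene_region(pid)
        regions.append(
            {"gene_id": pid, "chrom": g.chrom, "start": g.start, "end": g.end}
        )

    region_path = outdir / "gene_regions.tsv"
    pd.DataFrame(regions).to_csv(region_path, sep="\t", index=False)

    outcome_paths = {}
    for j, oid in enumerate(outcomes):
        parts = []
        for i, pid in enumerate(proteins):
            pair_spec = specs.get((pid, oid))
            if pair_spec is None:
                continue
            panel, pspec = panels[pid]
            pair_spec = simulate.replace_spec(
                pair_spec, chrom=chrom_of[pid],
                seed=seed + 1000 * i + 17 * (j + 1),
            )
            parts.append(
                simulate.simulate_outcome_gwas(
                    panel, pair_spec, exposure_truth[pid]
                )
            )
        path = outdir / f"outcome_{oid}.tsv"
        summary_io.write_summary(pd.concat(parts, ignore_index=True), path)
        outcome_paths[oid] = str(path)

    return PipelineConfig(
        proteins=pconfigs,
        outcomes=outcome_paths,
        gene_regions=str(region_path),
        output_dir=str(outdir / "results"),
        seed=seed,
        **config_overrides,
    )


def run_synthetic_study(
    specs: dict[tuple[str, str], simulate.ScenarioSpec],
    outdir,
    seed: int = 0,
    **config_overrides,
) -> pd.DataFrame:
    """Generate inputs via the synthetic-data module, then run the pipeline."""
    config = write_synthetic_study(specs, outdir, seed, **config_overrides)
    return run_pipeline(config)
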