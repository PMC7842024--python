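"""End-to-end orchestration: QC -> diversity/hemizygosity -> LD -> structure
-> year scan -> core collection, from a single validated configuration.

Every stochastic step (null-pair sampling, bootstrap resampling, random
representatives, simulation) draws from streams derived from the single
``RunConfig.seed``, so a rerun with the same configuration writes
byte-identical outputs. The run report is a JSON object of headline numbers
plus a sha256 checksum per written file; it carries no timestamps.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import core as core_mod
from . import io as io_mod
from . import ld as ld_mod
from . import qc as qc_mod
from . import structure as structure_mod
from .containers import GenotypeMatrix
from .simulate import SimConfig, SubgenomeSpec, YieldParams, simulate_panel

logger = logging.getLogger("hexapop")

REPORT_SCHEMA_VERSION = 1

_KNOWN_KEYS = {
    "snp_path", "pav_path", "hits_path", "phenotype_path", "out_dir", "seed",
    "simulate", "filter", "ld", "structure", "scan", "core",
}
_SECTION_KEYS = {
    "simulate": {
        "n_accessions", "n_subpops", "fst", "subgenome_sizes", "ld_decay_bp",
        "hemizygous_fraction", "het_call_prob", "missing_rate", "pav_fraction",
        "inbreeding", "phenotype_effects", "base_year", "year_noise_sd",
        "year_range", "year_missing_rate", "yield_params", "multi_hit_rate", "tie_rate",
    },
    "filter": {"mvf_min", "call_rate_min_snp", "require_unique_mapping"},
    "ld": {"max_distance", "n_null_pairs", "n_pcs", "r2_block_threshold",
           "max_pairs", "min_complete", "spline_df", "cluster_blocks"},
    "structure": {"n_pcs", "n_bootstrap", "n_groups", "tau", "min_size"},
    "scan": {"n_pcs", "mvf_min", "min_informative"},
    "core": {"g_max", "yield_column"},
}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclasses.dataclass
class RunConfig:
    """Validated pipeline configuration (unknown keys rejected)."""

    out_dir: str
    seed: int = 0
    snp_path: str | None = None
    pav_path: str | None = None
    hits_path: str | None = None
    phenotype_path: str | None = None
    simulate: dict | None = None
    filter: dict = dataclasses.field(default_factory=dict)
    ld: dict = dataclasses.field(default_factory=dict)
    structure: dict = dataclasses.field(default_factory=dict)
    scan: dict = dataclasses.field(default_factory=dict)
    core: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for section, allowed in _SECTION_KEYS.items():
            sub = d.get(section)
            if sub is not None:
                bad = set(sub) - allowed
                if bad:
                    raise ValueError(f"unknown keys in {section!r}: {sorted(bad)}")
        if "out_dir" not in d:
            raise ValueError("config requires out_dir")
        if d.get("simulate") is None and (d.get("snp_path") is None or d.get("hits_path") is None):
            raise ValueError("config needs either a simulate section or snp_path + hits_path")
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def sim_config(self) -> SimConfig:
        d = dict(self.simulate or {})
        d.pop("multi_hit_rate", None)
        d.pop("tie_rate", None)
        if "subgenome_sizes" in d:
            d["subgenome_sizes"] = {
                sg: SubgenomeSpec(*v) if not isinstance(v, SubgenomeSpec) else v
                for sg, v in d["subgenome_sizes"].items()
            }
        if "yield_params" in d and not isinstance(d["yield_params"], YieldParams):
            d["yield_params"] = YieldParams(**d["yield_params"])
        if "phenotype_effects" in d:
            d["phenotype_effects"] = [tuple(e) for e in d["phenotype_effects"]]
        if "year_range" in d:
            d["year_range"] = tuple(d["year_range"])
        return SimConfig(seed=self.seed, **d)


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, str(exc)) from exc
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


@_stage("load_inputs")
def _load_inputs(config: RunConfig, out: Path):
    if config.simulate is not None:
        sim_cfg = config.sim_config()
        panel = simulate_panel(
            sim_cfg,
            multi_hit_rate=config.simulate.get("multi_hit_rate", 0.3),
            tie_rate=config.simulate.get("tie_rate", 0.05),
        )
        inputs = out / "inputs"
        inputs.mkdir(parents=True, exist_ok=True)
        io_mod.write_marker_csv(panel.snp, inputs / "markers_snp.csv")
        if panel.pav is not None:
            io_mod.write_marker_csv(panel.pav, inputs / "markers_pav.csv")
        io_mod.write_hit_table(panel.hits, inputs / "hits.tsv")
        io_mod.write_phenotypes(panel.phenotypes, inputs / "phenotypes.tsv")
        panel.truth.to_json(inputs / "truth.json")
        return panel.snp, panel.pav, panel.hits, panel.phenotypes
    snp = io_mod.read_marker_csv(config.snp_path, "snp")
    pav = io_mod.read_marker_csv(config.pav_path, "pav") if config.pav_path else None
    hits = io_mod.read_hit_table(config.hits_path)
    pheno = io_mod.read_phenotypes(config.phenotype_path) if config.phenotype_path else None
    return snp, pav, hits, pheno


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the run report (also written to
    ``out_dir/report.json``). Stage failures raise :class:`StageError`."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": config.seed,
        "stages": {},
        "outputs": {},
    }
    written: dict[str, Path] = {}

    snp, pav, hits, pheno = _load_inputs(config, out)

    # ---- QC / filtering --------------------------------------------------
    @_stage("qc")
    def do_qc():
        fcfg = qc_mod.FilterConfig(**config.filter)
        res = {}
        for name, gm in (("snp", snp), ("pav", pav)):
            if gm is None:
                continue
            # the hit file covers both datasets; restrict before deriving info
            own = hits[hits["marker_id"].isin(set(gm.marker_ids))]
            info = io_mod.derive_marker_info(own, gm)
            fr = qc_mod.filter_markers(gm, info, fcfg)
            res[name] = (fr.genotypes, info.loc[fr.genotypes.marker_ids], fr.audit)
        return res

    filtered = do_qc()
    snp_f, snp_info, snp_audit = filtered["snp"]
    report["stages"]["qc"] = {k: v[2] for k, v in filtered.items()}
    audit_path = out / "filter_audit.json"
    io_mod.write_report(report["stages"]["qc"], audit_path)
    written["filter_audit"] = audit_path
    if snp_f.n_markers < 2:
        raise StageError("qc", "fewer than 2 SNP markers retained; relax the filters")

    # ---- diversity + hemizygosity ---------------------------------------
    @_stage("diversity")
    def do_diversity():
        summary, tests = qc_mod.subgenome_summaries(snp_f, snp_info)
        summary.to_csv(out / "subgenome_summary.tsv", sep="\t", index=False)
        tests.to_csv(out / "subgenome_tests.tsv", sep="\t", index=False)
        written["subgenome_summary"] = out / "subgenome_summary.tsv"
        written["subgenome_tests"] = out / "subgenome_tests.tsv"
        hemi = qc_mod.hemizygosity_diagnostics(snp_f, snp_info)
        pd.Series(hemi.flagged, name="marker_id").to_csv(out / "hemizygous_flags.tsv", sep="\t", index=False)
        written["hemizygous_flags"] = out / "hemizygous_flags.tsv"
        return summary, hemi

    summary, hemi = do_diversity()
    report["stages"]["diversity"] = {
        "n_markers_by_subgenome": {
            r["name"]: int(r["n_markers"]) for _, r in summary[summary["level"] == "subgenome"].iterrows()
        },
        "median_adjacent_distance_by_subgenome": {
            r["name"]: r["median_adjacent_distance"] for _, r in summary[summary["level"] == "subgenome"].iterrows()
        },
        "hemizygosity_chi2_p": hemi.chi2_p,
        "n_flagged_hemizygous": len(hemi.flagged),
    }

    # ---- kinship / PCoA --------------------------------------------------
    @_stage("kinship")
    def do_kinship():
        K = structure_mod.dice_kinship(snp_f)
        K.to_csv(out / "kinship_snp.tsv", sep="\t")
        written["kinship"] = out / "kinship_snp.tsv"
        ord_res = structure_mod.pcoa(K)
        ord_res.coordinates.to_csv(out / "pcoa_coordinates.tsv", sep="\t")
        written["pcoa"] = out / "pcoa_coordinates.tsv"
        return K, ord_res

    K, ord_res = do_kinship()
    report["stages"]["kinship"] = {
        "n_accessions": int(K.shape[0]),
        "pco1_fraction": float(ord_res.eigenvalues[0] / ord_res.eigenvalues[ord_res.eigenvalues > 0].sum()),
    }

    # ---- LD --------------------------------------------------------------
    @_stage("ld")
    def do_ld():
        lcfg = dict(config.ld)
        n_pcs = lcfg.get("n_pcs", 3)
        pcs = ord_res.coordinates.iloc[:, :n_pcs].to_numpy() if n_pcs else None
        table = ld_mod.pairwise_ld(
            snp_f, snp_info,
            max_distance=lcfg.get("max_distance", 2.0e7),
            pcs=pcs,
            max_pairs=lcfg.get("max_pairs", 20000),
            min_complete=lcfg.get("min_complete", 30),
            seed=config.seed,
        )
        table.to_csv(out / "ld_pairs.tsv", sep="\t", index=False)
        written["ld_pairs"] = out / "ld_pairs.tsv"
        null = ld_mod.unlinked_null(
            snp_f, snp_info, n_pairs=lcfg.get("n_null_pairs", 10000),
            pcs=pcs, min_complete=lcfg.get("min_complete", 30), seed=config.seed,
        )
        decay = ld_mod.fit_decay(table, null.q95, df=lcfg.get("spline_df", 12.0))
        with open(out / "ld_decay.json", "w") as fh:
            json.dump({**decay.to_dict(), "seed": config.seed}, fh, indent=1)
        written["ld_decay"] = out / "ld_decay.json"
        blocks = None
        if lcfg.get("cluster_blocks", True):
            blocks = ld_mod.cluster_markers_ld(
                snp_f, snp_info, r2_threshold=lcfg.get("r2_block_threshold", 0.2),
                pcs=pcs, min_complete=lcfg.get("min_complete", 30),
            )
            blocks.membership.to_csv(out / "ld_block_membership.tsv", sep="\t", index=False)
            io_mod.write_bed(
                blocks.blocks.rename(columns={"representative": "name"}), out / "ld_blocks.bed"
            )
            written["ld_blocks"] = out / "ld_blocks.bed"
            written["ld_block_membership"] = out / "ld_block_membership.tsv"
        return null, decay, blocks

    null, decay, blocks = do_ld()
    report["stages"]["ld"] = {
        "n_pairs": int(decay.n_pairs),
        "null_q95": null.q95,
        "decay_distance_bp": decay.decay_distance,
        "decay_censored": decay.censored,
        "n_blocks": None if blocks is None else int(len(blocks.blocks)),
    }

    # ---- population structure -------------------------------------------
    @_stage("structure")
    def do_structure():
        scfg = dict(config.structure)
        grp = structure_mod.stable_groups(
            snp_f,
            n_bootstrap=scfg.get("n_bootstrap", 100),
            n_groups=scfg.get("n_groups"),
            tau=scfg.get("tau", 0.7),
            min_size=scfg.get("min_size", 5),
            seed=config.seed,
        )
        assign = grp.labels.to_frame()
        assign.to_csv(out / "group_assignment.tsv", sep="\t")
        grp.stability.to_csv(out / "group_stability.tsv", sep="\t", index=False)
        written["group_assignment"] = out / "group_assignment.tsv"
        written["group_stability"] = out / "group_stability.tsv"
        return grp

    grp = do_structure()
    report["stages"]["structure"] = {
        "n_groups_reference": grp.params["n_groups"],
        "n_stable_groups": grp.n_stable,
        "n_grouped_accessions": int((grp.labels > 0).sum()),
    }

    # ---- year scan -------------------------------------------------------
    if pheno is not None and "year" in pheno.columns and pheno["year"].notna().sum() >= 30:
        @_stage("year_scan")
        def do_scan():
            scan = structure_mod.year_scan(
                snp_f, pheno["year"].dropna(),
                n_pcs=config.scan.get("n_pcs", 3),
                mvf_min=config.scan.get("mvf_min", 0.05),
                min_informative=config.scan.get("min_informative", 10),
            )
            scan.to_csv(out / "year_scan.tsv", sep="\t")
            written["year_scan"] = out / "year_scan.tsv"
            return scan

        scan = do_scan()
        tested = scan["p_adj"].dropna()
        report["stages"]["year_scan"] = {
            "n_tested": int(len(tested)),
            "n_significant_p_adj_0.05": int((tested < 0.05).sum()),
            "top_marker": tested.idxmin() if len(tested) else None,
            "top_p_adj": float(tested.min()) if len(tested) else None,
        }
    else:
        report["stages"]["year_scan"] = {"skipped": "no usable year phenotype"}

    # ---- core collection -------------------------------------------------
    @_stage("core")
    def do_core():
        ycol = config.core.get("yield_column", "yield_A1")
        yields = pheno[ycol] if (pheno is not None and ycol in pheno.columns) else None
        part = core_mod.optimal_partition(K, g_max=config.core.get("g_max"))
        part = core_mod.select_representatives(part, yields, seed=config.seed)
        part.curve.to_csv(out / "core_gscan.tsv", sep="\t", index=False)
        part.representatives.to_csv(out / "core_collection.tsv", sep="\t", index=False)
        written["core_gscan"] = out / "core_gscan.tsv"
        written["core_collection"] = out / "core_collection.tsv"
        cmp_res = core_mod.core_vs_whole_distribution(K, part.core_ids)
        return part, cmp_res

    part, cmp_res = do_core()
    report["stages"]["core"] = {
        "optimal_g": part.g,
        "avg_within_kinship": part.avg_within_kinship,
        "core_fraction": part.g / K.shape[0],
        "core_vs_whole_chi2_p": cmp_res.p_value,
    }

    report["outputs"] = {name: io_mod.file_checksum(p) for name, p in sorted(written.items())}
    io_mod.write_report(report, out / "report.json")
    return report
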