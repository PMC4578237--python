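"""End-to-end orchestration: simulate -> qc -> infer -> decode -> bin -> map
-> blup -> jointqtl, driven by one config and one seed.

Every stage writes its outputs under the configured directory; when the run
starts from a simulated panel the truth-comparison metrics (breakpoint
precision/recall, origin accuracy, map-length error, QTL detection) are
written alongside.  All randomness is routed through the config seed's named
streams, so two runs with the same config are identical.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (bin_builder, evaluation, genetic_map, genotype_hmm, io_formats,
               joint_linkage, parental_inference, phenotype_blup, qc_outliers,
               synthetic_data)

_KNOWN_KEYS = {
    "seed", "outdir", "stages", "n_families", "rils_per_family", "chromosomes",
    "snp_density", "maf", "selfing_generations", "missing_rate", "error_rate",
    "het_undercall_rate", "qtl", "n_envs", "n_reps", "h2", "epsilon", "rho",
    "p_min", "min_families_composite", "alpha", "n_permutations",
    "n_contaminants", "n_excess_het",
}


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "nambin_out"
    stages: list = field(default_factory=lambda: [
        "simulate", "qc", "binmap", "map", "blup", "jointqtl"])
    n_families: int = 2
    rils_per_family: int = 100
    chromosomes: list = field(default_factory=lambda: [["chr1", 200_000_000, 200.0]])
    snp_density: float = 5e-5
    maf: float = 0.5
    selfing_generations: int = 6
    missing_rate: float = 0.3
    error_rate: float = 0.01
    het_undercall_rate: float = 0.5
    qtl: list = field(default_factory=list)   # [{chrom, pos, effect} or {.., effects: {fam: e}}]
    n_envs: int = 6
    n_reps: int = 2
    h2: float = 0.9
    epsilon: float = 0.01
    rho: float = 2.0
    p_min: float = 0.99
    min_families_composite: int = 0
    alpha: float = 0.05
    n_permutations: int = 200
    n_contaminants: int = 0
    n_excess_het: int = 0

    @classmethod
    def from_yaml(cls, path):
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def sim_config(self):
        return synthetic_data.SimConfig(
            n_families=self.n_families, rils_per_family=self.rils_per_family,
            chromosomes=[tuple(c) for c in self.chromosomes],
            snp_density=self.snp_density, maf=self.maf,
            selfing_generations=self.selfing_generations,
            missing_rate=self.missing_rate, error_rate=self.error_rate,
            het_undercall_rate=self.het_undercall_rate, seed=self.seed)


class StageError(RuntimeError):
    def __init__(self, stage, cause):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config):
    """Run the configured stages; returns a dict of result objects."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    state = {}
    for stage in config.stages:
        fn = _STAGES.get(stage)
        if fn is None:
            raise StageError(stage, "unknown stage")
        try:
            fn(config, state, out)
        except Exception as exc:          # noqa: BLE001 - named-stage reporting
            raise StageError(stage, exc) from exc
    return state


def _stage_simulate(config, state, out):
    scfg = config.sim_config()
    founders, truth, clean, noisy = synthetic_data.simulate_panel(scfg)
    if config.n_contaminants or config.n_excess_het:
        noisy, labels = synthetic_data.inject_outliers(
            noisy, config.n_contaminants, config.n_excess_het,
            rng=scfg.rng("outliers"))
        state["outlier_labels"] = labels
    qtl = []
    for q in config.qtl:
        effects = q.get("effects")
        if effects is None:
            effects = {f: q["effect"] for f in scfg.family_names()}
        qtl.append({"chrom": q["chrom"], "pos": q["pos"], "effects": effects})
    truth.qtl = qtl
    pheno = synthetic_data.simulate_phenotype(
        truth, noisy.family_of, qtl, n_envs=config.n_envs, n_reps=config.n_reps,
        h2=config.h2, rng=scfg.rng("phenotype"))
    state.update(founders=founders, truth=truth, matrix=noisy, phenotypes=pheno,
                 sim_config=scfg)
    io_formats.write_genotypes(noisy, out / "genotypes.hmp")
    io_formats.write_families(noisy.family_of, out / "families.csv")
    io_formats.write_truth(truth, out / "truth.json")
    io_formats.write_phenotypes(pheno, out / "phenotypes.csv")


def _stage_qc(config, state, out):
    matrix = state["matrix"]
    scfg = state.get("sim_config") or config.sim_config()
    founder_m = synthetic_data.founder_genotype_matrix(state["founders"], scfg)
    reports, _ = qc_outliers.nj_contaminant_scan(matrix, founder_m)
    reports += qc_outliers.excess_het_scan(matrix)
    pd.DataFrame([{"line": r.line, "reason": r.reason, **r.evidence}
                  for r in reports]).to_csv(out / "qc_report.csv", index=False)
    state["qc_reports"] = reports
    state["matrix"] = qc_outliers.remove_outliers(matrix, reports)


def _stage_binmap(config, state, out):
    matrix = state["matrix"]
    scfg = state.get("sim_config") or config.sim_config()
    params = genotype_hmm.HMMParams(epsilon=config.epsilon, rho=config.rho,
                                    p_min=config.p_min)
    chrom_info = {c[0]: (c[1], c[2]) for c in scfg.chromosomes}
    state["bin_maps"] = {}
    state["decoded"] = {}
    for fam in matrix.families():
        fam_m = parental_inference.prefilter_family_sites(matrix.family_matrix(fam))
        pa = parental_inference.infer_and_refine(
            fam_m, rng=scfg.rng("refine", fam))
        origins, site_idx = parental_inference.origin_coded_calls(fam_m, pa)
        retained = fam_m.sites.iloc[site_idx].reset_index(drop=True)
        decoded = _decode_by_chrom(origins, retained, chrom_info, params)
        skeleton, imputed, unresolved = bin_builder.family_bin_map(
            decoded, np.arange(len(retained)), retained, fam_m.lines,
            scfg.chromosomes, params)
        io_formats.write_bin_map(imputed, out / f"binmap_{fam}.bed")
        state["bin_maps"][fam] = imputed
        state["decoded"][fam] = (decoded, retained, fam_m.lines)
        if unresolved:
            (out / f"binmap_{fam}_unresolved.txt").write_text(
                "\n".join(f"{r}\t{c}" for r, c in unresolved))
    if "truth" in state:
        metrics = {}
        for fam, bm in state["bin_maps"].items():
            metrics[fam] = evaluation.match_breakpoints(bm, state["truth"])
        state["breakpoint_metrics"] = metrics
        (out / "breakpoint_metrics.json").write_text(json.dumps(metrics, indent=1))


def _decode_by_chrom(origins, retained, chrom_info, params):
    blocks = []
    for c in retained["chrom"].unique():
        mask = (retained["chrom"] == c).to_numpy()
        pos_cm = retained["pos"].to_numpy()[mask] / chrom_info[c][0] * chrom_info[c][1]
        blocks.append(genotype_hmm.decode_ril(origins[:, mask], pos_cm, params))
    return np.hstack(blocks)


def _stage_map(config, state, out):
    scfg = state.get("sim_config") or config.sim_config()
    state["family_maps"] = {}
    for fam, bm in state["bin_maps"].items():
        gmap = genetic_map.build_family_map(bm)
        io_formats.write_genetic_map(gmap, out / f"map_{fam}.csv")
        state["family_maps"][fam] = gmap
    # composite over families from decoded origins on the union of sites
    origin_ms, positions = _union_origins(state)
    keep, lines, encoding = genetic_map.select_composite_markers(
        origin_ms, positions, min_families=config.min_families_composite)
    chrom_lengths = {c[0]: c[1] for c in scfg.chromosomes}
    joint = genetic_map.composite_bins(
        encoding, positions.loc[keep].reset_index(drop=True), chrom_lengths, lines)
    composite = genetic_map.assemble_composite_map(joint)
    io_formats.write_genetic_map(composite, out / "map_composite.csv")
    state["composite_map"] = composite
    state["composite_bins"] = joint
    if "truth" in state:
        true_cm = {c[0]: c[2] for c in scfg.chromosomes}
        err = {fam: evaluation.map_length_error(gmap, true_cm)
               for fam, gmap in state["family_maps"].items()}
        (out / "map_metrics.json").write_text(json.dumps(err, indent=1))
        state["map_metrics"] = err


def _union_origins(state):
    """Per-family origins at the union of retained sites.

    Each family's error-corrected, imputed bin map is expanded back to SNP
    coordinates so every family reports an origin at every union site it is
    polymorphic for; sites outside a family's own retained set (monomorphic
    there, or filtered) stay missing for that family.
    """
    frames = []
    for fam, (decoded, retained, lines) in state["decoded"].items():
        frames.append(retained[["chrom", "pos"]])
    positions = (pd.concat(frames).drop_duplicates().sort_values(["chrom", "pos"])
                 .reset_index(drop=True))
    origin_ms = {}
    for fam, (decoded, retained, lines) in state["decoded"].items():
        bm = state["bin_maps"][fam]
        own = set(zip(retained["chrom"], retained["pos"]))
        full = np.full((len(lines), len(positions)), -1, dtype=np.int8)
        for chrom in positions["chrom"].unique():
            mask = (positions["chrom"] == chrom).to_numpy()
            pos = positions["pos"].to_numpy()[mask]
            codes = bin_builder.expand_to_sites(bm, chrom, pos)
            org = np.where(codes == bin_builder.CODE_NA, -1,
                           (codes == bin_builder.CODE_DIVERSE).astype(np.int8))
            informative = np.array([(chrom, p) in own for p in pos])
            org[:, ~informative] = -1
            full[:, mask] = org
        origin_ms[fam] = (lines, full)
    return origin_ms, positions


def _stage_blup(config, state, out):
    pheno = state["phenotypes"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        comp = phenotype_blup.estimate_components(pheno)
        blups = phenotype_blup.blup_lines(pheno, comp)
    blups.to_csv(out / "blups.csv")
    h2 = phenotype_blup.h2_mean_basis(comp)
    (out / "heritability.json").write_text(json.dumps(
        {"H2_mean_basis": h2, "var_g": comp.var_g, "var_ge": comp.var_ge,
         "var_e": comp.var_e}))
    state["blups"] = blups
    state["components"] = comp


def _stage_jointqtl(config, state, out):
    scfg = state.get("sim_config") or config.sim_config()
    jb = state["composite_bins"]
    # composite codes: 1 = common allele -> 0 doses of the diverse allele
    codes = np.where(jb.genotypes == bin_builder.CODE_NA, bin_builder.CODE_NA,
                     np.where(jb.genotypes == 1, 0, 2)).astype(np.int8)
    blups = state["blups"]
    lines = [l for l in jb.lines if l in blups.index]
    rows = [jb.lines.index(l) for l in lines]
    family_of = state["matrix"].family_of
    positions = jb.bins.assign(pos=((jb.bins["start"] + jb.bins["end"]) // 2))
    panel = joint_linkage.MarkerPanel(codes[rows], lines, family_of,
                                      positions=positions[["chrom", "pos"]])
    y = blups.loc[lines].to_numpy()
    model, thr = joint_linkage.joint_linkage_scan(
        y, panel, alpha=config.alpha, n_perm=config.n_permutations,
        rng=scfg.rng("permutations"))
    result = {
        "p_enter": thr.p_enter,
        "qtl": [
            {
                "marker": int(k),
                "chrom": str(positions["chrom"].iloc[k]),
                "peak_bp": int(positions["pos"].iloc[k]),
                "interval": {kk: (int(v) if isinstance(v, (int, np.integer)) else v)
                             for kk, v in model.intervals[k].items()
                             if kk in ("bp_lo", "bp_hi", "truncated", "peak_lod")},
                "effects": model.effects[k].to_dict(orient="records"),
            }
            for k in model.selected
        ],
    }
    (out / "qtl_model.json").write_text(json.dumps(result, indent=1))
    pd.DataFrame([
        {"marker": q["marker"], "chrom": q["chrom"], "peak_bp": q["peak_bp"],
         "ci_lo_bp": q["interval"].get("bp_lo"), "ci_hi_bp": q["interval"].get("bp_hi"),
         "peak_lod": q["interval"].get("peak_lod")}
        for q in result["qtl"]]).to_csv(out / "qtl.csv", index=False)
    state["qtl_model"] = model
    state["qtl_threshold"] = thr


_STAGES = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "binmap": _stage_binmap,
    "map": _stage_map,
    "blup": _stage_blup,
    "jointqtl": _stage_jointqtl,
}
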