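"""End-to-end orchestration of the analysis graph on synthetic or user data.

``run_fc_pipeline`` reproduces the functional-connectivity arm: per-session
FC matrices -> metric curves -> group AUC permutation tests per timepoint
and on change-over-time curves (with BH-corrected one-sample tests across
the 10 sparsity levels), edge-wise FDR + network-based statistics, a-priori
node strength with mixed ANOVA, and within-network analyses.

``run_morphometry_pipeline`` covers the structural arm: regional volume
tables, the CV audit with Kruskal-Wallis, and the FA change statistics.

Every stochastic stage draws its seed from a master seed so reruns with the
same configuration are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import inference
from .connectivity import fc_from_timecourses
from .graphs import DEFAULT_SPARSITY_LEVELS, METRIC_NAMES, metric_curves, \
    network_mean_fc, node_strength, weighted_efficiency
from .parcellation import ANXIETY_SEEDS, DEFAULT_NETWORKS
from .simulate import (SimulationConfig, TIMEPOINTS, make_cohort,
                       simulate_fa_table, simulate_regional_volumes,
                       simulate_timecourses)

__all__ = ["PipelineConfig", "run_fc_pipeline", "run_morphometry_pipeline"]


@dataclass
class PipelineConfig:
    """Run-time options for the orchestrated pipelines."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    sparsity_levels: tuple[float, ...] = DEFAULT_SPARSITY_LEVELS
    n_permutations: int = 1000
    nbs_threshold: float = 2.0
    master_seed: int = 0
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        return cls(simulation=sim, **raw)

    def family_seed(self, family: str) -> int:
        """Deterministic per-test-family seed derived from the master seed."""
        h = hashlib.sha256(f"{self.master_seed}:{family}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31 - 1)

    def config_hash(self) -> str:
        payload = {"simulation": asdict(self.simulation),
                   "sparsity_levels": list(self.sparsity_levels),
                   "n_permutations": self.n_permutations,
                   "nbs_threshold": self.nbs_threshold,
                   "master_seed": self.master_seed}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _group_split(items: dict, meta: dict) -> tuple[list, list]:
    wt = [v for k, v in items.items() if meta[k[0]] == "wildtype"]
    ko = [v for k, v in items.items() if meta[k[0]] == "knockout"]
    return wt, ko


def run_fc_pipeline(cfg: PipelineConfig) -> dict:
    """Functional-connectivity arm on a synthetic cohort; returns a
    JSON-serialisable result bundle keyed by analysis stage."""
    sim = cfg.simulation
    subjects = make_cohort(sim)
    sessions = simulate_timecourses(sim, subjects)
    genotype = {s.subject_id: s.genotype for s in subjects}
    fcs = {k: fc_from_timecourses(tc) for k, tc in sessions.items()}
    curves = {k: metric_curves(fc, cfg.sparsity_levels)
              for k, fc in fcs.items()}

    results: dict = {"config_hash": cfg.config_hash(),
                     "n_subjects": len(genotype)}

    # per-timepoint AUC permutation tests (Bonferroni over 3 metrics at
    # the reporting layer)
    auc_tests = {}
    for tp in TIMEPOINTS:
        for metric in METRIC_NAMES:
            wt = [curves[k][metric] for k in curves
                  if k[1] == tp and genotype[k[0]] == "wildtype"]
            ko = [curves[k][metric] for k in curves
                  if k[1] == tp and genotype[k[0]] == "knockout"]
            res = inference.AUCPermutationTest(wt, ko, metric=metric).fit(
                n_permutations=cfg.n_permutations,
                seed=cfg.family_seed(f"auc:{tp}:{metric}"))
            auc_tests[f"{tp}:{metric}"] = {
                "p": res.p_value, "diff": res.observed_diff,
                "p_bonferroni": min(1.0, res.p_value * len(METRIC_NAMES)),
                "group_means": list(res.group_means), "seed": res.seed,
                "n_permutations": res.n_permutations}
    results["auc_tests"] = auc_tests

    # change over time: per-subject curve difference, AUC test between
    # genotypes plus BH-corrected one-sample tests across sparsity levels
    change_tests = {}
    sids = sorted({k[0] for k in curves})
    paired = [s for s in sids if (s, TIMEPOINTS[0]) in curves
              and (s, TIMEPOINTS[1]) in curves]
    for metric in METRIC_NAMES:
        deltas = {
            s: curves[(s, TIMEPOINTS[1])][metric].values
            - curves[(s, TIMEPOINTS[0])][metric].values
            for s in paired}
        dmat = np.array([deltas[s] for s in paired])
        x = np.asarray(cfg.sparsity_levels, dtype=float)
        d_aucs = {s: float(np.trapezoid(deltas[s], x)) for s in paired}
        wt = [d_aucs[s] for s in paired if genotype[s] == "wildtype"]
        ko = [d_aucs[s] for s in paired if genotype[s] == "knockout"]
        res = inference.AUCPermutationTest(wt, ko, metric=metric).fit(
            n_permutations=cfg.n_permutations,
            seed=cfg.family_seed(f"auc-change:{metric}"))
        from scipy import stats as _st
        tvals, pvals = _st.ttest_1samp(dmat, 0.0, axis=0)
        qvals = np.full_like(pvals, np.nan)
        ok = np.isfinite(pvals)
        if ok.any():  # zero-variance levels yield NaN p and are skipped
            qvals[ok] = inference.benjamini_hochberg(pvals[ok])
        change_tests[metric] = {
            "genotype_p": res.p_value, "genotype_diff": res.observed_diff,
            "seed": res.seed,
            "per_level": [
                {"sparsity": float(lv), "delta_mean": float(m),
                 "t": float(t), "p": float(p), "q": float(q)}
                for lv, m, t, p, q in zip(x, dmat.mean(axis=0), tvals,
                                          pvals, qvals)]}
    results["change_tests"] = change_tests

    # edge-wise FDR and NBS per timepoint
    edge_nbs = {}
    for tp in TIMEPOINTS:
        keys = [k for k in fcs if k[1] == tp]
        wt = [fcs[k] for k in keys if genotype[k[0]] == "wildtype"]
        ko = [fcs[k] for k in keys if genotype[k[0]] == "knockout"]
        stats_ = inference.edgewise_ttests(wt, ko)
        mats = wt + ko
        labels = ["wildtype"] * len(wt) + ["knockout"] * len(ko)
        nbs = inference.NetworkBasedStatistic(
            mats, labels, threshold=cfg.nbs_threshold).fit(
            n_permutations=cfg.n_permutations,
            seed=cfg.family_seed(f"nbs:{tp}"))
        edge_nbs[tp] = {
            "n_fdr_significant": len(stats_.significant_edges(0.05)),
            "fdr_edges": stats_.significant_edges(0.05),
            "nbs_components": [
                {"nodes": sorted(c), "edges": e, "p": float(p)}
                for (c, e), p in zip(nbs.components, nbs.p_values)],
            "nbs_max_component_edges": nbs.max_component_edges,
            "nbs_seed": nbs.seed}
    results["edgewise_nbs"] = edge_nbs

    # a-priori node strength + mixed ANOVA per timepoint
    strength = {}
    for tp in TIMEPOINTS:
        frames = [node_strength(fcs[k], ANXIETY_SEEDS) for k in fcs
                  if k[1] == tp]
        df = pd.concat(frames, ignore_index=True)
        df["genotype"] = df["subject_id"].map(genotype)
        aov = inference.MixedANOVA(df, dv="value", within="region",
                                   between="genotype",
                                   subject="subject_id").fit()
        strength[tp] = {k: v for k, v in aov.effects.items()}
    results["node_strength_anova"] = strength

    # within-network mean FC and weighted efficiency, genotype t-tests
    from scipy import stats as _st
    nets = {}
    for net in DEFAULT_NETWORKS.values():
        per_tp = {}
        for tp in TIMEPOINTS:
            keys = [k for k in fcs if k[1] == tp]
            mfc = {g: [] for g in ("wildtype", "knockout")}
            eff = {g: [] for g in ("wildtype", "knockout")}
            for k in keys:
                g = genotype[k[0]]
                mfc[g].append(network_mean_fc(fcs[k], net))
                eff[g].append(weighted_efficiency(fcs[k], net))
            out = {}
            for label, vals in (("mean_fc", mfc), ("weighted_efficiency",
                                                   eff)):
                t, p = _st.ttest_ind(vals["wildtype"], vals["knockout"])
                out[label] = {"t": float(t), "p": float(p),
                              "mean_wt": float(np.mean(vals["wildtype"])),
                              "mean_ko": float(np.mean(vals["knockout"]))}
            per_tp[tp] = out
        nets[net.name] = per_tp
    results["networks"] = nets

    if cfg.output_dir:
        _write_bundle(results, cfg, "fc_results.json")
    return results


def run_morphometry_pipeline(cfg: PipelineConfig) -> dict:
    """Structural arm: volume tables + CV audit + Kruskal-Wallis, and the
    FA longitudinal-change statistics."""
    sim = cfg.simulation
    subjects = make_cohort(sim)
    volumes = simulate_regional_volumes(sim, subjects)
    fa = simulate_fa_table(sim, subjects)

    results: dict = {"config_hash": cfg.config_hash()}

    from .morphometry import region_cv
    cv_tests = {}
    for tp in TIMEPOINTS:
        sub = volumes[volumes.timepoint == tp]
        cv = region_cv(sub, group_cols="genotype")
        groups = [g["cv"].to_numpy() for _, g in cv.groupby("genotype")]
        h, p = inference.kruskal_wallis(groups)
        cv_tests[tp] = {
            "kruskal_H": h, "kruskal_p": p,
            "n_regions": int(cv.region.nunique()),
            "median_cv": {g: float(d["cv"].median())
                          for g, d in cv.groupby("genotype")}}
    results["volume_cv"] = cv_tests

    change = inference.longitudinal_change(fa)
    results["fa_change"] = {
        "n_dropped": change.n_dropped,
        "regions": change.table.to_dict(orient="records")}

    fa_df = fa.copy()
    fa_wide = fa_df.pivot_table(index=["subject_id", "genotype", "region"],
                                columns="timepoint", values="value")
    fa_wide["delta"] = fa_wide["adulthood"] - fa_wide["adolescence"]
    aov = inference.MixedANOVA(fa_wide.reset_index(), dv="delta",
                               within="region", between="genotype",
                               subject="subject_id").fit()
    results["fa_change_anova"] = aov.effects

    if cfg.output_dir:
        _write_bundle(results, cfg, "morphometry_results.json")
    return results


def _write_bundle(results: dict, cfg: PipelineConfig, name: str) -> None:
    from .io import write_json

    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_json(results, out / name)
    write_json({"config_hash": results["config_hash"],
                "master_seed": cfg.master_seed,
                "n_permutations": cfg.n_permutations}, out / "provenance.json")
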