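"""End-to-end pipeline orchestration.

Stages (simulate -> clean -> network -> metrics -> modules -> nbs ->
stats -> subtype) communicate only through serialized artifacts inside
a run directory, so any stage can be re-run from its predecessors'
outputs. A JSON manifest records the configuration and seeds; reruns
with an identical configuration are bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import community, cohort, metrics, nbs, network, preprocess, stats, subtype

logger = logging.getLogger(__name__)

STAGES = ("simulate", "clean", "network", "metrics", "modules", "nbs", "stats", "subtype")


@dataclass
class PipelineConfig:
    """Validated configuration for a full pipeline run.

    Defaults are sized for a desk-scale run (reduced null-model and
    permutation counts); raise ``n_null`` and ``nbs_n_perm`` for
    publication-scale normalization and NBS inference.
    """

    seed: int = 0
    cohort: dict = field(default_factory=dict)  # CohortSpec overrides
    sparsity_grid: list[float] = field(
        default_factory=lambda: list(np.round(np.arange(0.10, 0.301, 0.01), 2))
    )
    tau_grid: list[float] = field(
        default_factory=lambda: list(np.round(np.arange(0.50, 0.701, 0.01), 2))
    )
    reference_sparsity: float = 0.20
    n_null: int = 20
    n_swaps_per_edge: int = 10
    nbs_primary_f: float = 12.0
    nbs_n_perm: int = 1000
    scrub_rule: str = "and"
    fd_thresh: float = 0.5
    dvars_thresh: float = 0.5
    band_low: float = 0.01
    band_high: float = 0.08
    k_range: tuple[int, int] = (2, 6)
    input_dir: str | None = None  # read an existing cohort instead of simulating

    def __post_init__(self) -> None:
        grid = np.asarray(self.sparsity_grid, float)
        if (grid <= 0).any() or (grid >= 1).any() or not (np.diff(grid) > 0).all():
            raise ValueError("sparsity grid must be strictly increasing within (0, 1)")
        taus = np.asarray(self.tau_grid, float)
        if (taus <= 0).any() or (taus > 1).any() or not (np.diff(taus) > 0).all():
            raise ValueError("tau grid must be strictly increasing within (0, 1]")
        if not (0 < self.reference_sparsity < 1):
            raise ValueError("reference sparsity must be in (0, 1)")
        if self.n_null < 1 or self.nbs_n_perm < 1:
            raise ValueError("replicate counts must be positive")
        if self.nbs_primary_f <= 0:
            raise ValueError("NBS primary threshold must be positive")
        if self.scrub_rule not in ("and", "or"):
            raise ValueError("scrub_rule must be 'and' or 'or'")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**(data or {}))

    def cohort_spec(self) -> cohort.CohortSpec:
        kwargs = dict(self.cohort)
        kwargs.setdefault("seed", self.seed)
        if "module_sizes" in kwargs:
            kwargs["module_sizes"] = tuple(kwargs["module_sizes"])
        return cohort.CohortSpec(**kwargs)


def _subdir(rundir: Path, stage: str) -> Path:
    d = rundir / stage
    d.mkdir(parents=True, exist_ok=True)
    return d


def stage_simulate(cfg: PipelineConfig, rundir: Path) -> Path:
    out = _subdir(rundir, "simulate")
    spec = cfg.cohort_spec()
    records, ts_sets, motions = cohort.generate_cohort(spec)
    cohort.write_cohort(out, spec, records, ts_sets, motions)
    return out

def stage_clean(cfg: PipelineConfig, rundir: Path) -> Path:
    src = Path(cfg.input_dir) if cfg.input_dir else rundir / "simulate"
    out = _subdir(rundir, "clean")
    (out / "signals").mkdir(exist_ok=True)
    table, ts_sets, motions = cohort.read_cohort(src)
    table.to_csv(out / "subjects.tsv", sep="\t", index=False)
    atlas = src / "atlas.tsv"
    if atlas.exists():
        pd.read_csv(atlas, sep="\t").to_csv(out / "atlas.tsv", sep="\t", index=False)
    qc_reports = []
    for ts, mot in zip(ts_sets, motions):
        cleaned, qc = preprocess.clean_pipeline(
            ts,
            mot,
            fd_thresh=cfg.fd_thresh,
            dvars_thresh=cfg.dvars_thresh,
            scrub_rule=cfg.scrub_rule,
            low=cfg.band_low,
            high=cfg.band_high,
        )
        qc_reports.append(qc.to_dict())
        np.savetxt(
            out / "signals" / f"{ts.subject_id}.tsv",
            cleaned.data,
            delimiter="\t",
            fmt="%.6f",
        )
        np.savetxt(
            out / "signals" / f"{ts.subject_id}.mask.tsv",
            cleaned.valid_mask.astype(int)[:, None],
            delimiter="\t",
            fmt="%d",
        )
    with open(out / "qc.json", "w") as fh:
        json.dump(qc_reports, fh, indent=2)
    return out


def _load_clean(rundir: Path, tr: float) -> tuple[pd.DataFrame, list[cohort.RoiTimeSeriesSet]]:
    cdir = rundir / "clean"
    table = pd.read_csv(cdir / "subjects.tsv", sep="\t")
    ts_sets = []
    for sid in table["subject_id"]:
        data = pd.read_csv(cdir / "signals" / f"{sid}.tsv", sep="\t", header=None).to_numpy(float)
        mask = (
            pd.read_csv(cdir / "signals" / f"{sid}.mask.tsv", sep="\t", header=None)
            .to_numpy(int)
            .ravel()
            .astype(bool)
        )
        ts_sets.append(
            cohort.RoiTimeSeriesSet(subject_id=sid, data=data, tr_seconds=tr, valid_mask=mask)
        )
    return table, ts_sets


def stage_network(cfg: PipelineConfig, rundir: Path) -> Path:
    out = _subdir(rundir, "network")
    spec = cfg.cohort_spec()
    table, ts_sets = _load_clean(rundir, spec.tr_seconds)
    zs = []
    for ts in ts_sets:
        cm = network.correlation_matrix(ts)
        zs.append(cm.z)
        np.savetxt(out / f"{ts.subject_id}.z.tsv", cm.z, delimiter="\t", fmt="%.5f")
    np.save(out / "z_stack.npy", np.stack(zs))  # compact cache alongside TSVs
    table.to_csv(out / "subjects.tsv", sep="\t", index=False)
    return out


def _load_network(rundir: Path) -> tuple[pd.DataFrame, np.ndarray]:
    ndir = rundir / "network"
    table = pd.read_csv(ndir / "subjects.tsv", sep="\t")
    z = np.load(ndir / "z_stack.npy")
    return table, z


def stage_metrics(cfg: PipelineConfig, rundir: Path) -> Path:
    out = _subdir(rundir, "metrics")
    table, z = _load_network(rundir)
    grid = network.SparsityGrid(np.asarray(cfg.sparsity_grid))
    rng = np.random.default_rng(cfg.seed + 1)
    rows = []
    nodal_deg_auc, nodal_eff_auc = [], []
    for si, sid in enumerate(table["subject_id"]):
        cm = network.ConnectivityMatrix(z=z[si])
        per_thr = []
        degs, effs = [], []
        for s in grid:
            g = network.binarize(cm, float(s))
            gm = metrics.global_metrics(
                g,
                n_null=cfg.n_null,
                seed=int(rng.integers(2**31 - 1)),
                n_swaps_per_edge=cfg.n_swaps_per_edge,
            )
            per_thr.append(gm.as_dict())
            nm = metrics.nodal_metrics(g)
            degs.append(nm.degree)
            effs.append(nm.efficiency)
        curves = metrics.metric_curves(grid, per_thr)
        row = {"subject_id": sid}
        row.update({f"{k}_auc": c.auc for k, c in curves.items()})
        rows.append(row)
        gv = grid.values
        nodal_deg_auc.append([metrics.auc_trapezoid(gv, np.array(d)) for d in np.array(degs).T])
        nodal_eff_auc.append([metrics.auc_trapezoid(gv, np.array(e)) for e in np.array(effs).T])
    pd.DataFrame(rows).to_csv(out / "global_auc.tsv", sep="\t", index=False)
    np.savetxt(out / "nodal_degree_auc.tsv", np.array(nodal_deg_auc), delimiter="\t", fmt="%.6f")
    np.savetxt(out / "nodal_efficiency_auc.tsv", np.array(nodal_eff_auc), delimiter="\t", fmt="%.6f")
    return out


def stage_modules(cfg: PipelineConfig, rundir: Path) -> Path:
    out = _subdir(rundir, "modules")
    table, z = _load_network(rundir)
    atlas_path = rundir / "clean" / "atlas.tsv"
    atlas_labels = atlas_names = None
    if atlas_path.exists():
        atlas = pd.read_csv(atlas_path, sep="\t")
        atlas_labels = atlas["module_id"].to_numpy()
        atlas_names = list(dict.fromkeys(atlas["module_name"]))
    graphs = [
        network.binarize(network.ConnectivityMatrix(z=z[i]), cfg.reference_sparsity)
        for i in range(len(table))
    ]
    hc_mask = (table["group"] == "HC").to_numpy()
    hc_graphs = [g for g, m in zip(graphs, hc_mask) if m]
    parts = community.hc_reference_partitions(
        hc_graphs,
        taus=np.asarray(cfg.tau_grid),
        atlas_labels=atlas_labels,
        atlas_names=atlas_names,
    )
    best = community.best_partition(parts)
    pd.DataFrame(
        {
            "node": np.arange(len(best.labels)),
            "module_id": best.labels,
            "module_name": (
                np.asarray(best.module_names)[best.labels]
                if best.module_names
                else best.labels
            ),
        }
    ).to_csv(out / "partition.tsv", sep="\t", index=False)
    with open(out / "partition_meta.json", "w") as fh:
        json.dump(
            {
                "q": best.q,
                "tau": best.source_tau,
                "n_modules": best.n_modules,
                "module_sizes": best.module_sizes().tolist(),
                "q_by_tau": {str(p.source_tau): p.q for p in parts},
            },
            fh,
            indent=2,
        )
    # per-tau modular metrics; module counts can differ across taus, so
    # inter-module connectivity is aligned by module NAME and integrated
    # over the tau grid for pairs present at every tau
    taus = np.array([p.source_tau for p in parts])
    part_metrics = [[community.modular_metrics(g, p) for p in parts] for g in graphs]

    def _pair_values(mm, part) -> dict[tuple[str, str], float]:
        names = part.module_names or [str(s) for s in mm.module_ids]
        vals: dict[tuple[str, str], list[float]] = {}
        for ai in range(len(mm.module_ids)):
            for bi in range(ai + 1, len(mm.module_ids)):
                key = tuple(sorted((names[ai], names[bi])))
                vals.setdefault(key, []).append(float(mm.inter_conn[ai, bi]))
        return {k: float(np.mean(v)) for k, v in vals.items()}

    per_subject_pairs = [
        [_pair_values(mm, p) for mm, p in zip(per_tau, parts)]
        for per_tau in part_metrics
    ]
    common = set(per_subject_pairs[0][0])
    for per_tau in per_subject_pairs:
        for d in per_tau:
            common &= set(d)
    rows = []
    for si, sid in enumerate(table["subject_id"]):
        for key in sorted(common):
            series = np.array([d[key] for d in per_subject_pairs[si]])
            auc = (
                metrics.auc_trapezoid(taus, series) if len(taus) >= 2 else float(series[0])
            )
            rows.append(
                {"subject_id": sid, "module_a": key[0], "module_b": key[1], "auc": auc}
            )
    pd.DataFrame(rows).to_csv(out / "intermodule_auc.tsv", sep="\t", index=False)
    rows = []
    for si, sid in enumerate(table["subject_id"]):
        pt = part_metrics[si]
        wd = np.stack([m.within_degree for m in pt])
        pc = np.stack([m.participation for m in pt])
        rows.append(
            {
                "subject_id": sid,
                "mean_within_degree": float(wd.mean()),
                "mean_participation": float(pc.mean()),
            }
        )
    pd.DataFrame(rows).to_csv(out / "modular_summary.tsv", sep="\t", index=False)
    return out


def stage_nbs(cfg: PipelineConfig, rundir: Path) -> Path:
    out = _subdir(rundir, "nbs")
    table, z = _load_network(rundir)
    covars = np.column_stack(
        [table["age"].to_numpy(float), stats.encode_gender(table["gender"].to_numpy())]
    )
    result = nbs.nbs_anova(
        z,
        table["group"].to_numpy(),
        primary_f=cfg.nbs_primary_f,
        n_perm=cfg.nbs_n_perm,
        seed=cfg.seed + 2,
        covariates=covars,
    )
    np.savetxt(out / "null_max_component.tsv", result.null_sizes[:, None], fmt="%d")
    rows = []
    for ci, comp in enumerate(result.components):
        for i, j in comp.edges:
            rows.append(
                {
                    "component": ci,
                    "node_i": int(i),
                    "node_j": int(j),
                    "F": float(result.f_matrix[i, j]),
                    "size": comp.size,
                    "p_corrected": comp.p_corrected,
                }
            )
    pd.DataFrame(rows).to_csv(out / "components.tsv", sep="\t", index=False)
    return out


def stage_stats(cfg: PipelineConfig, rundir: Path) -> Path:
    out = _subdir(rundir, "stats")
    table = pd.read_csv(rundir / "clean" / "subjects.tsv", sep="\t")
    groups = table["group"].to_numpy()
    age = table["age"].to_numpy(float)
    gender = table["gender"].to_numpy()
    # demographics
    chi2, p_gender = stats.gender_chisq(
        pd.crosstab(table["group"], table["gender"]).to_numpy()
    )
    f_age, p_age = stats.oneway_anova(age, groups)
    with open(out / "demographics.json", "w") as fh:
        json.dump(
            {"gender_chi2": chi2, "gender_p": p_gender, "age_F": f_age, "age_p": p_age},
            fh,
            indent=2,
        )
    # global metric AUCs: Bonferroni over the seven measures
    gtab = pd.read_csv(rundir / "metrics" / "global_auc.tsv", sep="\t")
    gmetrics = gtab[[f"{m}_auc" for m in metrics.GLOBAL_METRIC_NAMES]]
    results = stats.group_metric_anova(
        gmetrics, groups, age, gender, correction="bonferroni", family_size=7
    )
    stats.comparison_table(results).to_csv(out / "global_anova.tsv", sep="\t", index=False)
    # nodal metrics: FDR across nodes
    for name in ("degree", "efficiency"):
        nod = np.loadtxt(rundir / "metrics" / f"nodal_{name}_auc.tsv", delimiter="\t")
        fps = []
        for col in range(nod.shape[1]):
            resid = stats.residualize(nod[:, col], age, gender)
            fps.append(stats.oneway_anova(resid, groups))
        pvals = np.array([p for _, p in fps])
        corr = stats.correct(pvals, method="fdr")
        pd.DataFrame(
            {
                "node": np.arange(nod.shape[1]),
                "F": [f for f, _ in fps],
                "p": pvals,
                "p_fdr": corr.p_adjusted,
                "significant": corr.reject,
            }
        ).to_csv(out / f"nodal_{name}_anova.tsv", sep="\t", index=False)
    return out


def stage_subtype(cfg: PipelineConfig, rundir: Path) -> Path:
    out = _subdir(rundir, "subtype")
    table = pd.read_csv(rundir / "clean" / "subjects.tsv", sep="\t")
    patients = table[table["group"].isin(cohort.PATIENT_GROUPS)]
    scores = patients[list(subtype.SCALE_COLUMNS)].to_numpy(float)
    sol = subtype.subtype_patients(scores, k_range=range(cfg.k_range[0], cfg.k_range[1] + 1))
    report = subtype.retest_concordance(scores, sol.labels, sol.k, seed=cfg.seed + 3)
    pd.DataFrame(
        {
            "subject_id": patients["subject_id"].to_numpy(),
            "cluster": sol.labels,
            "subtype": sol.subtype_names if sol.subtype_names is not None else sol.labels,
        }
    ).to_csv(out / "labels.tsv", sep="\t", index=False)
    idx_rows = [{"k": k, **v} for k, v in sol.indices.items()]
    pd.DataFrame(idx_rows).to_csv(out / "indices.tsv", sep="\t", index=False)
    with open(out / "report.json", "w") as fh:
        json.dump(
            {
                "k_selected": sol.k,
                "votes": sol.votes,
                "weak_structure": sol.weak_structure,
                "ari_kmedoids": report.ari_kmedoids,
                "ari_fuzzy_cmeans": report.ari_fuzzy_cmeans,
                "fcm_converged": report.fcm_converged,
                "linkage_heights": sol.linkage_record[:, 2].tolist(),
            },
            fh,
            indent=2,
        )
    return out


STAGE_FUNCS = {
    "simulate": stage_simulate,
    "clean": stage_clean,
    "network": stage_network,
    "metrics": stage_metrics,
    "modules": stage_modules,
    "nbs": stage_nbs,
    "stats": stage_stats,
    "subtype": stage_subtype,
}


def run_pipeline(
    cfg: PipelineConfig, rundir: str | Path, stages: tuple[str, ...] = STAGES
) -> Path:
    """Execute the requested stages in order, recording a manifest."""
    rundir = Path(rundir)
    rundir.mkdir(parents=True, exist_ok=True)
    manifest = {"config": dataclasses.asdict(cfg), "stages": []}
    for stage in STAGES:
        if stage not in stages:
            continue
        if stage == "simulate" and cfg.input_dir:
            continue
        logger.info("running stage %s", stage)
        try:
            STAGE_FUNCS[stage](cfg, rundir)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"].append(stage)
    manifest["config"]["sparsity_grid"] = [float(v) for v in cfg.sparsity_grid]
    manifest["config"]["tau_grid"] = [float(v) for v in cfg.tau_grid]
    with open(rundir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return rundir
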