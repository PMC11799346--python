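"""End-to-end orchestration: simulate/ingest -> prep -> relate -> cluster
-> structure -> mtdna -> report.

Stages run in dependency order from a single :class:`RunConfig`; every
stochastic stage consumes a seed derived from the run seed, all seeds are
recorded in the run manifest, and each stage writes machine-readable TSV/
JSON outputs into the run directory.  A stage failure halts the run with a
stage-named error; outputs of completed stages are preserved.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from demekin import genio, kinclust, mtdna, relatedness, simulate, structure


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything one analysis run needs, ingestible from YAML."""

    out_dir: str = "demekin_run"
    seed: int = 0
    # inputs: either file paths or a simulation config
    beagle_path: str | None = None
    fasta_path: str | None = None
    metadata_path: str | None = None
    sim: simulate.SimConfig | None = None
    # stage toggles
    stages: list[str] = field(
        default_factory=lambda: ["prep", "relate", "cluster", "structure", "mtdna"]
    )
    # stage options
    min_mean_depth: float = 2.0
    polymorphic_only: bool = True
    relate_mode: str = "jacquard9"
    relate_call: bool = False
    nboot: int = 1000
    au_threshold: float = 0.95
    k_min: int = 1
    k_max: int = 3
    admix_runs: int = 3
    n_perm: int = 1000
    mt_distance: str = "diff"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim_raw is not None:
            cfg.sim = simulate.SimConfig(**sim_raw)
        return cfg


def _stage_seed(seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages and return the machine-readable summary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "stages": {}, "stage_seeds": {}}
    truth_meta: pd.DataFrame | None = None

    # ---- inputs -----------------------------------------------------------
    try:
        if config.sim is not None:
            sim_cfg = config.sim
            cohort = simulate.simulate_cohort(sim_cfg)
            gl = simulate.simulate_genotype_likelihoods(cohort[1], sim_cfg)
            files = simulate.write_fixture_bundle(cohort, gl, out / "simulated")
            config.beagle_path = str(files["beagle"])
            config.fasta_path = str(files["mtdna"])
            config.metadata_path = str(files["metadata"])
            summary["stages"]["simulate"] = {
                "n_individuals": len(cohort[0]),
                "files": {k: str(v) for k, v in files.items()},
            }
    except Exception as exc:  # noqa: BLE001 - stage-named rethrow
        raise StageError("simulate", exc)

    if config.metadata_path:
        truth_meta = pd.read_csv(config.metadata_path, sep="\t", dtype={"id": str})

    gl = freqs = None
    # ---- prep -------------------------------------------------------------
    if "prep" in config.stages:
        try:
            gl = genio.read_beagle(config.beagle_path)
            if gl.mean_depth is None and truth_meta is not None and "mean_depth" in truth_meta:
                depth = truth_meta.set_index("id")["mean_depth"]
                gl.mean_depth = depth.reindex(gl.ids).to_numpy(dtype=float)
            raw_freqs = genio.estimate_allele_frequencies(gl)
            gl, filter_log = genio.apply_filters(
                gl,
                raw_freqs,
                min_mean_depth=config.min_mean_depth,
                polymorphic_only=config.polymorphic_only,
            )
            freqs = genio.estimate_allele_frequencies(gl)
            filter_log.excluded_individuals.to_csv(
                out / "excluded_individuals.tsv", sep="\t", index=False
            )
            filter_log.excluded_sites.to_csv(
                out / "excluded_sites.tsv", sep="\t", index=False
            )
            summary["stages"]["prep"] = {
                "n_individuals": gl.n_individuals,
                "n_sites": gl.n_sites,
                "n_polymorphic": int(raw_freqs.polymorphic.sum()),
                "n_excluded_individuals": len(filter_log.excluded_individuals),
            }
        except Exception as exc:
            raise StageError("prep", exc)

    pairs = None
    # ---- relate -----------------------------------------------------------
    if "relate" in config.stages and gl is not None:
        try:
            seed = _stage_seed(config.seed, "relate")
            summary["stage_seeds"]["relate"] = seed
            pairs = relatedness.pairwise_relatedness(
                gl, freqs, mode=config.relate_mode, call=config.relate_call, seed=seed
            )
            pairs.to_csv(out / "relatedness.tsv", sep="\t", index=False)
            flagged = relatedness.flag_r1_outliers(pairs)
            if flagged:
                pairs = pairs[
                    ~pairs["id_x"].isin(flagged) & ~pairs["id_y"].isin(flagged)
                ]
            po_calls = []
            if truth_meta is not None and "mother" in truth_meta:
                known = [
                    (str(r["mother"]), str(r["id"]))
                    for _, r in truth_meta.iterrows()
                    if isinstance(r.get("mother"), str) and r["mother"]
                ]
                key = {frozenset(p) for p in known}
                is_known = pairs.apply(
                    lambda r: frozenset((r["id_x"], r["id_y"])) in key, axis=1
                )
                if is_known.sum() >= 2:
                    ranges = relatedness.calibrate_po_ranges(pairs[is_known])
                    classified = relatedness.classify_po(pairs[~is_known], ranges)
                    classified.to_csv(out / "po_classification.tsv", sep="\t", index=False)
                    po_calls = classified.loc[
                        classified["is_po"], ["id_x", "id_y"]
                    ].values.tolist()
            summary["stages"]["relate"] = {
                "n_dyads": len(pairs),
                "r1_outliers": flagged,
                "po_calls": po_calls,
            }
        except Exception as exc:
            raise StageError("relate", exc)

    # ---- cluster ----------------------------------------------------------
    if "cluster" in config.stages and pairs is not None:
        try:
            seed = _stage_seed(config.seed, "cluster")
            summary["stage_seeds"]["cluster"] = seed
            tree, support = kinclust.relatedness_dendrogram(
                pairs, nboot=config.nboot, seed=seed
            )
            clusters, unassigned = kinclust.significant_clusters(
                tree, support, config.au_threshold
            )
            support.table.to_csv(out / "cluster_support.tsv", sep="\t", index=False)
            (out / "dendrogram.nwk").write_text(tree.to_newick(support.au()))
            diet_p = None
            if truth_meta is not None and "diet" in truth_meta and len(clusters) >= 2:
                diet = dict(zip(truth_meta["id"], truth_meta["diet"]))
                tab = kinclust.diet_cluster_table(diet, clusters)
                tab.to_csv(out / "diet_by_cluster.tsv", sep="\t")
                if tab.shape[0] >= 2 and tab.to_numpy().sum() > 0:
                    diet_p = kinclust.fisher_exact_rxc(tab.to_numpy())
            summary["stages"]["cluster"] = {
                "n_significant": len(clusters),
                "clusters": [
                    {k: c[k] for k in ("node", "members", "au", "depth")}
                    for c in clusters
                ],
                "unassigned": unassigned,
                "diet_fisher_p": diet_p,
            }
        except Exception as exc:
            raise StageError("cluster", exc)

    # ---- structure --------------------------------------------------------
    if "structure" in config.stages and gl is not None:
        try:
            seed = _stage_seed(config.seed, "structure")
            summary["stage_seeds"]["structure"] = seed
            pca = structure.pcangsd_pca(gl, freqs)
            pd.DataFrame(pca.covariance, index=gl.ids, columns=gl.ids).to_csv(
                out / "covariance.tsv", sep="\t"
            )
            runs: dict[int, list[structure.AdmixtureResult]] = {}
            for k in range(config.k_min, config.k_max + 1):
                runs[k] = [
                    structure.admixture_em(gl, k, seed=seed + 100 * k + r, freqs=freqs)
                    for r in range(config.admix_runs)
                ]
                best = max(runs[k], key=lambda r: r.loglik)
                pd.DataFrame(
                    best.Q, index=gl.ids, columns=[f"Q{j + 1}" for j in range(k)]
                ).to_csv(out / f"admixture_K{k}.tsv", sep="\t")
            ktab = structure.compare_k_runs(runs)
            ktab.to_csv(out / "k_comparison.tsv", sep="\t", index=False)
            best_k = int(ktab.loc[ktab["rank"] == 1, "K"].iloc[0])
            best_res = max(runs[best_k], key=lambda r: r.loglik)
            groups = None
            if truth_meta is not None and "deme" in truth_meta:
                groups = dict(zip(truth_meta["id"], truth_meta["deme"].astype(str)))
            rc = structure.residual_correlation(gl, best_res, freqs, groups=groups)
            pd.DataFrame(rc.correlation, index=rc.ids, columns=rc.ids).to_csv(
                out / "residual_correlation.tsv", sep="\t"
            )
            summary["stages"]["structure"] = {
                "pc_variance_fraction": pca.variance_fraction[:4].tolist(),
                "k_table": ktab.to_dict(orient="records"),
                "best_k": best_k,
            }
        except Exception as exc:
            raise StageError("structure", exc)

    # ---- mtdna ------------------------------------------------------------
    if "mtdna" in config.stages and config.fasta_path:
        try:
            seed = _stage_seed(config.seed, "mtdna")
            summary["stage_seeds"]["mtdna"] = seed
            aln = genio.read_fasta_alignment(config.fasta_path)
            vt = mtdna.call_variant_sites(aln)
            hgs = mtdna.assign_haplogroups(vt)
            pd.DataFrame(
                {"id": list(hgs.assignment), "haplogroup": list(hgs.assignment.values())}
            ).to_csv(out / "haplogroups.tsv", sep="\t", index=False)
            net = mtdna.median_joining_network(hgs)
            edges = pd.DataFrame(
                [
                    {"a": a, "b": b, "steps": d["weight"]}
                    for a, b, d in net.graph.edges(data=True)
                ]
            )
            edges.to_csv(out / "network_edges.tsv", sep="\t", index=False)
            amova_summary = None
            if truth_meta is not None and "deme" in truth_meta:
                groups = dict(zip(truth_meta["id"], truth_meta["deme"].astype(str)))
                res = mtdna.amova_phist(
                    hgs,
                    groups,
                    n_perm=config.n_perm,
                    seed=seed,
                    distance=config.mt_distance,
                )
                if res.pairwise is not None:
                    res.pairwise.to_csv(out / "amova_pairwise.tsv", sep="\t", index=False)
                amova_summary = {
                    "phi_st": res.phi_st,
                    "p_value": res.p_value,
                    "sigma_among": res.sigma_among,
                    "sigma_within": res.sigma_within,
                }
            summary["stages"]["mtdna"] = {
                "n_variable": vt.n_variable,
                "n_singleton": int(vt.singleton.sum()),
                "n_haplogroups": len(hgs.labels),
                "amova": amova_summary,
            }
        except Exception as exc:
            raise StageError("mtdna", exc)

    manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "stage_seeds": summary["stage_seeds"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return summary
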