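"""End-to-end orchestration: filter -> distance -> tree -> admixture ->
clones -> panel (-> maturity), with a JSON run manifest.

Every random draw in a run flows from the seeds recorded in the
manifest, so two runs with the same config are identical (the manifest
carries no timestamps). Each stage writes its artifacts as plain TSV /
newick / VCF under the output directory.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import admixture, distance, genio, njtree, panel, sitefilter, synonymy
from . import maturity as maturity_mod
from . import sim
from .core import ClonekitError, ParameterError


@dataclass
class PipelineConfig:
    """Run configuration; mirrors the YAML layout (one block per stage)."""

    vcf: str = ""
    metadata: str = ""
    assay: str = ""
    outdir: str = "clonekit_out"
    seed: int = 0
    filter: dict = field(default_factory=lambda: {
        "max_missing": 10, "missing_mode": "count",
        "min_maf": 0.05, "thin_bp": 1,
    })
    bootstrap: int = 1000
    admixture: dict = field(default_factory=lambda: {
        "k_min": 1, "k_max": 10, "restarts": 5,
        "max_iter": 300, "tol": 1e-5,
    })
    synonymy: dict = field(default_factory=lambda: {
        "max_extra": 2, "cutoff": None,
    })
    panel: dict = field(default_factory=dict)
    simulate: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ParameterError(f"unknown config keys: {sorted(bad)}")
        cfg = cls(**raw)
        for block in ("filter", "admixture", "synonymy"):
            merged = dict(getattr(cls(), block))
            merged.update(getattr(cfg, block) or {})
            setattr(cfg, block, merged)
        return cfg


class StageError(ClonekitError):
    def __init__(self, stage: str, cause: Exception, manifest: dict):
        self.stage = stage
        self.manifest = manifest
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")


def simulate_inputs(cfg: PipelineConfig) -> tuple[str, str]:
    """Materialise a synthetic cohort (VCF + metadata + truth TSVs)
    from the ``simulate`` config block; returns the two input paths."""
    s = dict(cfg.simulate)
    pools = sim.simulate_pools(
        k_pools=int(s.get("k_pools", 2)),
        n_sites=int(s.get("n_sites", 2000)),
        fst=float(s.get("fst", 0.3)),
        seed=int(s.get("seed", cfg.seed)),
    )
    spec = sim.CohortSpec(
        n_per_pool=tuple(s.get("n_per_pool", (10, 10))),
        hybrids=[tuple(h) for h in s.get("hybrids", [])],
        clone_groups=[tuple(c) for c in s.get("clone_groups", [])],
        n_sites=int(s.get("n_sites", 2000)),
        noise=tuple(s.get("noise", (0.05, 0.005, 0.05))),
        mislabel_fraction=float(s.get("mislabel_fraction", 0.0)),
        unknown_fraction=float(s.get("unknown_fraction", 0.0)),
        seed=int(s.get("seed", cfg.seed)),
    )
    G, samples, truth = sim.simulate_cohort(spec, pools)
    sites = sim.default_site_table(spec.n_sites)
    os.makedirs(cfg.outdir, exist_ok=True)
    vcf_path = os.path.join(cfg.outdir, "simulated.vcf")
    meta_path = os.path.join(cfg.outdir, "simulated_samples.tsv")
    genio.write_vcf(G, sites, vcf_path)
    genio.write_sample_metadata(samples, meta_path)
    truth_groups = synonymy.CloneGrouping(
        cutoff=float("nan"),
        groups=sorted([g for g in truth.clone_partition if len(g) >= 2],
                      key=lambda g: (-len(g), g)),
        singletons=sorted(
            g[0] for g in truth.clone_partition if len(g) == 1
        ),
    )
    synonymy.write_clone_groups_tsv(
        truth_groups, os.path.join(cfg.outdir, "truth_clone_partition.tsv")
    )
    pd.DataFrame(
        truth.true_q,
        index=pd.Index(G.sample_ids, name="sample_id"),
        columns=[f"Q{k + 1}" for k in range(truth.true_q.shape[1])],
    ).to_csv(os.path.join(cfg.outdir, "truth_Q.tsv"), sep="\t")
    return vcf_path, meta_path


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage; write artifacts and return the manifest."""
    manifest: dict = {"config": asdict(cfg), "stages": {}}
    outdir = cfg.outdir
    os.makedirs(outdir, exist_ok=True)

    def _run(stage, fn):
        try:
            return fn()
        except Exception as exc:
            with open(os.path.join(outdir, "manifest.partial.json"), "w") as fh:
                json.dump(manifest, fh, indent=2, default=str)
            raise StageError(stage, exc, manifest) from exc

    def _load():
        vcf, meta = cfg.vcf, cfg.metadata
        if cfg.simulate:
            vcf, meta = simulate_inputs(cfg)
        for p in (vcf, meta):
            if not p or not os.path.exists(p):
                raise FileNotFoundError(f"input file missing: {p!r}")
        G, sites = genio.read_vcf(vcf)
        samples = genio.read_sample_metadata(meta, vcf_sample_ids=G.sample_ids)
        return G, sites, samples

    G, sites, samples = _run("load", _load)
    manifest["stages"]["load"] = {
        "n_samples": G.n_samples, "n_sites": G.n_sites,
    }

    def _filter():
        fc = sitefilter.FilterConfig(**cfg.filter)
        return sitefilter.apply_filters(G, sites, fc)

    G_f, sites_f, report = _run("filter", _filter)
    report.to_csv(os.path.join(outdir, "filter_report.tsv"),
                  sep="\t", index=False)
    manifest["stages"]["filter"] = dict(
        zip(report["stage"], (int(x) for x in report["sites_surviving"]))
    )

    D = _run("distance", lambda: distance.distance_matrix(G_f))
    distance.write_phylip(D, os.path.join(outdir, "distances.phy"))
    manifest["stages"]["distance"] = {
        "max": round(float(D.values.max()), 4),
        "mean": round(float(D.values[np.triu_indices(D.n, 1)].mean()), 4),
    }

    def _tree():
        tree = njtree.nj(D)
        if cfg.bootstrap > 0:
            reps = [
                njtree.nj(bd) for bd in distance.bootstrap_matrices(
                    G_f, cfg.bootstrap, seed=cfg.seed
                )
            ]
            njtree.bootstrap_support(tree, reps)
        return tree

    tree = _run("tree", _tree)
    with open(os.path.join(outdir, "nj_tree.nwk"), "w") as fh:
        fh.write(njtree.write_newick(tree) + "\n")
    manifest["stages"]["tree"] = {
        "n_tips": len(njtree.tip_labels(tree)), "bootstrap": cfg.bootstrap,
    }

    def _admix():
        a = cfg.admixture
        ks = range(int(a["k_min"]), int(a["k_max"]) + 1)
        best, logliks = admixture.admixture_scan(
            G_f, ks, restarts=int(a["restarts"]), seed=cfg.seed,
            max_iter=int(a["max_iter"]), tol=float(a["tol"]),
        )
        delta = admixture.evanno_delta_k(
            {k: v for k, v in logliks.items()}
        ) if len(logliks) >= 3 else None
        return best, logliks, delta

    best_fits, logliks, delta = _run("admixture", _admix)
    k_opt = admixture.best_k(delta) if delta is not None else max(
        logliks, key=lambda k: max(logliks[k])
    )
    fit = best_fits[k_opt]
    qdf = pd.DataFrame(
        fit.Q, index=pd.Index(G.sample_ids, name="sample_id"),
        columns=[f"Q{k + 1}" for k in range(fit.K)],
    )
    qdf["label"] = admixture.classify_membership(fit.Q)
    # long format ordered by tree tip order, ready for bar plots
    tip_order = njtree.tip_labels(tree)
    qdf.loc[tip_order].reset_index().melt(
        id_vars=["sample_id", "label"], var_name="cluster",
        value_name="ancestry",
    ).to_csv(os.path.join(outdir, "Q_long.tsv"), sep="\t", index=False)
    qdf.to_csv(os.path.join(outdir, "Q.tsv"), sep="\t")
    if delta is not None:
        delta.to_csv(os.path.join(outdir, "delta_k.tsv"),
                     sep="\t", index=False)
    manifest["stages"]["admixture"] = {
        "k_optimal": int(k_opt),
        "loglik": round(fit.loglik, 2),
        "n_admixed": int(sum(l == "admixed" for l in qdf["label"])),
    }

    def _clones():
        manual = cfg.synonymy.get("cutoff")
        if manual is not None:
            cutoff = float(manual)
            seeds = []
        else:
            seeds = synonymy.find_seed_groups(
                tree, samples, D,
                max_extra=int(cfg.synonymy.get("max_extra", 2)),
            )
            cutoff = synonymy.derive_cutoff(seeds)
        grouping = synonymy.clone_groups(D, cutoff)
        return seeds, cutoff, grouping

    seeds, cutoff, grouping = _run("clones", _clones)
    synonymy.write_clone_groups_tsv(
        grouping, os.path.join(outdir, "clone_groups.tsv")
    )
    report_syn = synonymy.classify_nomenclature(grouping, samples)
    pd.DataFrame(
        [{"group": gi, "names": "; ".join(names)}
         for gi, names in report_syn.synonym_sets]
    ).to_csv(os.path.join(outdir, "synonym_sets.tsv"), sep="\t", index=False)
    pd.DataFrame(
        [{"cultivar_name": n, "n_locations": c}
         for n, c in report_syn.homonyms.items()]
    ).to_csv(os.path.join(outdir, "homonyms.tsv"), sep="\t", index=False)
    pd.DataFrame(
        [{"sample_id": s, "suggested_name": v if v else "none"}
         for s, v in report_syn.unknown_suggestions.items()]
    ).to_csv(os.path.join(outdir, "unknown_suggestions.tsv"),
             sep="\t", index=False)
    manifest["stages"]["clones"] = {
        "cutoff": round(float(cutoff), 4),
        "n_seed_groups": len(seeds),
        **synonymy.grouping_summary(grouping),
    }

    def _panel():
        return panel.greedy_min_panel(G_f, sites_f)

    panel_res = _run("panel", _panel)
    panel_res.table.to_csv(os.path.join(outdir, "core_panel.tsv"),
                           sep="\t", index=False)
    manifest["stages"]["panel"] = {
        "panel_size": panel_res.size,
        "n_residual_pairs": len(panel_res.residual_pairs),
    }

    if cfg.assay:
        def _maturity():
            calls = maturity_mod.read_assay(cfg.assay)
            labels = qdf["label"].to_dict()
            return maturity_mod.tabulate_assay(calls, membership=labels)

        counts, crosstab = _run("maturity", _maturity)
        counts.to_csv(os.path.join(outdir, "maturity_counts.tsv"), sep="\t")
        if crosstab is not None:
            crosstab.to_csv(os.path.join(outdir, "maturity_by_cluster.tsv"),
                            sep="\t")
        manifest["stages"]["maturity"] = {c: int(v)
                                          for c, v in counts.items()}

    from . import __version__
    manifest["version"] = __version__
    manifest["seed"] = cfg.seed
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str, sort_keys=True)
    return manifest
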