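"""End-to-end orchestration: simulate -> detect -> cooccur -> associate -> enrich -> env_rf.

Each stage writes TSV outputs under a run directory and the run manifest
records the configuration hash, seeds and per-output row counts. Reruns with
an unchanged configuration are byte-identical (no timestamps are recorded);
a completed stage whose recorded hash matches the current configuration is
reused instead of recomputed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from itertools import combinations
from pathlib import Path

import pandas as pd

from hgtcooc import __version__, association, cooccurrence, detect, enrichment, env_rf
from hgtcooc.io import FixtureData, read_fixture, write_fixture
from hgtcooc.records import MGE_FLAG_NAMES
from hgtcooc.simulate import simulate_dataset

STAGES = ("simulate", "detect", "cooccur", "associate", "enrich", "env_rf")


@dataclass
class Thresholds:
    identity: float = 0.95
    recent_identity: float = 0.99
    coverage: float = 0.95
    region_min_len: int = 500
    min_contig: int = 5000
    breadth: float = 0.30
    prevalence: int = 10
    support: float = 0.75
    bh_alpha: float = 0.05
    env_rho: float = 0.95

    def validate(self) -> None:
        checks = [
            0.5 <= self.identity < 1.0,
            self.identity <= self.recent_identity <= 1.0,
            0.5 <= self.coverage <= 1.0,
            self.region_min_len >= 1,
            self.min_contig >= 0,
            0.0 <= self.breadth <= 1.0,
            self.prevalence >= 1,
            0.0 < self.support < 1.0,
            0.0 < self.bh_alpha < 1.0,
            0.0 < self.env_rho <= 1.0,
        ]
        if not all(checks):
            raise ValueError("threshold out of documented range")


@dataclass
class RunConfig:
    seed: int = 0
    simulate: dict = field(default_factory=dict)
    thresholds: Thresholds = field(default_factory=Thresholds)
    rf_trees: int = 300
    rf_null_replicates: int = 100
    rf_null_trees: int = 100
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in STAGES})

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data = dict(raw)
        if "thresholds" in data:
            tnames = {f.name for f in fields(Thresholds)}
            tunknown = set(data["thresholds"]) - tnames
            if tunknown:
                raise ValueError(f"unknown threshold keys: {sorted(tunknown)}")
            data["thresholds"] = Thresholds(**data["thresholds"])
        if "stages" in data:
            sunknown = set(data["stages"]) - set(STAGES)
            if sunknown:
                raise ValueError(f"unknown stages: {sorted(sunknown)}")
            merged = {s: True for s in STAGES}
            merged.update(data["stages"])
            data["stages"] = merged
        cfg = cls(**data)
        cfg.thresholds.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def analytic_hash(self) -> str:
        payload = {
            "seed": self.seed,
            "simulate": self.simulate,
            "thresholds": asdict(self.thresholds),
            "rf": [self.rf_trees, self.rf_null_replicates, self.rf_null_trees],
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def _stage_done(run_dir: Path, stage: str, cfg_hash: str) -> bool:
    marker = run_dir / stage / ".stage.json"
    if not marker.exists():
        return False
    return json.loads(marker.read_text()).get("config_hash") == cfg_hash


def _mark_stage(run_dir: Path, stage: str, cfg_hash: str, counts: dict[str, int]) -> None:
    (run_dir / stage / ".stage.json").write_text(
        json.dumps({"config_hash": cfg_hash, "rows": counts}, sort_keys=True, indent=1)
        + "\n"
    )


def _save(df: pd.DataFrame, path: Path, counts: dict[str, int], index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)
    counts[path.name] = len(df)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the configured stages; returns the run manifest (also written)."""
    run_dir = Path(out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.analytic_hash()
    thr = config.thresholds
    manifest: dict = {
        "config_hash": cfg_hash,
        "seed": config.seed,
        "version": __version__,
        "stages": {},
    }

    # ---- simulate --------------------------------------------------------
    fixture_dir = run_dir / "simulate" / "fixture"
    if config.stages["simulate"] and not _stage_done(run_dir, "simulate", cfg_hash):
        (run_dir / "simulate").mkdir(exist_ok=True)
        dataset = simulate_dataset(seed=config.seed, **config.simulate)
        write_fixture(dataset, fixture_dir)
        _mark_stage(
            run_dir,
            "simulate",
            cfg_hash,
            {"genomes": len(dataset.genomes), "events": len(dataset.truth.hgt_events)},
        )
    if not fixture_dir.exists():
        raise RuntimeError("stage simulate: fixture missing; run simulate first")
    data: FixtureData = read_fixture(fixture_dir)
    manifest["stages"]["simulate"] = {"genomes": len(data.genomes)}

    taxonomy = {g.genome_id: g.taxonomy for g in data.genomes}
    genomes_by_id = {g.genome_id: g for g in data.genomes}
    genes = {g.gene_id: g for gm in data.genomes for g in gm.genes()}
    contig_lengths = {c.contig_id: c.length for gm in data.genomes for c in gm.contigs}

    # ---- detect ----------------------------------------------------------
    ddir = run_dir / "detect"
    if config.stages["detect"] and not _stage_done(run_dir, "detect", cfg_hash):
        ddir.mkdir(exist_ok=True)
        counts: dict[str, int] = {}
        clusters = detect.cluster_genes(
            list(genes.values()), id_threshold=thr.identity, coverage=thr.coverage
        )
        cl_rows = [
            {
                "cluster_id": c.cluster_id,
                "gene_id": gid,
                "representative": c.representative_gene_id,
            }
            for c in clusters
            for gid in c.member_gene_ids
        ]
        _save(pd.DataFrame(cl_rows), ddir / "clusters.tsv", counts)
        rbh = detect.call_rbh_hgt(
            clusters, genes, taxonomy, contig_lengths,
            min_contig=thr.min_contig, min_identity=thr.identity,
        )
        _save(detect.events_to_frame(rbh), ddir / "events_rbh.tsv", counts)
        region_events = []
        ids = sorted(genomes_by_id)
        for a, b in combinations(ids, 2):
            if detect.assign_divergence_level(taxonomy[a], taxonomy[b]) == "within_genus":
                continue
            segs = detect.find_identity_segments(
                genomes_by_id[a], genomes_by_id[b],
                min_len=thr.region_min_len, min_id=thr.identity,
            )
            region_events.extend(
                detect.call_region_hgt(segs, genomes_by_id, taxonomy, min_contig=thr.min_contig)
            )
        _save(detect.events_to_frame(region_events), ddir / "events_region.tsv", counts)
        _save(
            detect.events_per_level(rbh, taxonomy).reset_index(),
            ddir / "events_per_level.tsv",
            counts,
        )
        _mark_stage(run_dir, "detect", cfg_hash, counts)
    if config.stages["cooccur"] or config.stages["associate"] or config.stages["enrich"]:
        if not (ddir / "events_rbh.tsv").exists():
            raise RuntimeError("stage detect: outputs missing; run detect first")
    events_df = pd.read_csv(ddir / "events_rbh.tsv", sep="\t") if (ddir / "events_rbh.tsv").exists() else pd.DataFrame()
    manifest["stages"]["detect"] = {"rbh_events": len(events_df)}

    rbh_events = [
        detect.HGTEvent(
            genome_a=r.genome_a,
            genome_b=r.genome_b,
            gene_a=r.gene_a,
            gene_b=r.gene_b,
            identity=float(r.identity),
            identity_bin=r.identity_bin,
            divergence_level=r.divergence_level,
            method=r.method,
            cluster_id=r.cluster_id,
        )
        for r in events_df.itertuples()
    ] if len(events_df) else []

    # ---- cooccur ---------------------------------------------------------
    cdir = run_dir / "cooccur"
    presence = cooccurrence.call_presence(
        data.samples.breadth, data.samples.rpkm, presence_threshold=thr.breadth
    )
    retained, empty = cooccurrence.filter_prevalence(
        presence.present, min_samples=thr.prevalence
    )
    present = cooccurrence.drop_empty_samples(presence.present[retained])
    hgt_genomes = {e.genome_a for e in rbh_events} | {e.genome_b for e in rbh_events}
    if config.stages["cooccur"] and not _stage_done(run_dir, "cooccur", cfg_hash):
        cdir.mkdir(exist_ok=True)
        counts = {}
        cooc = cooccurrence.hypergeom_cooccurrence(present, alpha=thr.bh_alpha)
        _save(cooc, cdir / "cooccurrence.tsv", counts)
        fracs = cooccurrence.classify_size_fraction(
            present,
            presence.rpkm.loc[present.index, retained],
            data.samples.fractions,
            support_threshold=thr.support,
        )
        _save(
            pd.DataFrame(
                [
                    {"genome_id": f.genome_id, "fraction_class": f.fraction_class,
                     "support": f.support}
                    for f in fracs
                ]
            ),
            cdir / "fraction_classes.tsv",
            counts,
        )
        flags = {g: g in hgt_genomes for g in present.columns}
        prev = cooccurrence.feature_prevalence(present, flags)
        _save(prev.rename("hgt_prevalence").reset_index(), cdir / "hgt_prevalence.tsv", counts)
        _mark_stage(run_dir, "cooccur", cfg_hash, counts)
    manifest["stages"]["cooccur"] = {"retained_genomes": len(retained)}

    # ---- associate -------------------------------------------------------
    if config.stages["associate"] and not _stage_done(run_dir, "associate", cfg_hash):
        adir = run_dir / "associate"
        adir.mkdir(exist_ok=True)
        counts = {}
        cooc = pd.read_csv(cdir / "cooccurrence.tsv", sep="\t")
        frac_df = pd.read_csv(cdir / "fraction_classes.tsv", sep="\t")
        fracs = [
            cooccurrence.FractionClass(r.genome_id, r.fraction_class, r.support, {})
            for r in frac_df.itertuples()
        ]
        env_medians = association.genome_env_medians(present, data.samples.env)
        table = association.build_pair_table(
            rbh_events, cooc, data.patristic, env_medians, fracs, taxonomy,
            retained_genomes=retained,
        )
        _save(table, adir / "pair_table.tsv", counts)
        env_t = [c for c in table.columns if c.endswith("_diff_t")]
        predictors_full = ["cooccur", "phylo_dist_t", *env_t, "fraction_class"]
        if table["hgt"].nunique() == 2:
            fits = {}
            for name, preds in {
                "full": predictors_full,
                "no_fraction": ["cooccur", "phylo_dist_t", *env_t],
                "no_env": ["cooccur", "phylo_dist_t"],
                "cooccur_only": ["cooccur"],
            }.items():
                try:
                    fits[name] = association.fit_logistic(table, preds)
                except ValueError:
                    continue
            if "full" in fits:
                _save(
                    fits["full"].coefficients.reset_index(names="term"),
                    adir / "coefficients_full.tsv",
                    counts,
                )
            if len(fits) > 1:
                _save(
                    association.compare_models(list(fits.values())),
                    adir / "model_comparison.tsv",
                    counts,
                )
            _save(
                association.vif(table, predictors_full)
                .rename_axis("term")
                .reset_index(),
                adir / "vif.tsv",
                counts,
            )
        _mark_stage(run_dir, "associate", cfg_hash, counts)
    manifest["stages"]["associate"] = {"done": config.stages["associate"]}

    # ---- enrich ----------------------------------------------------------
    if config.stages["enrich"] and not _stage_done(run_dir, "enrich", cfg_hash):
        edir = run_dir / "enrich"
        edir.mkdir(exist_ok=True)
        counts = {}
        cl_df = pd.read_csv(ddir / "clusters.tsv", sep="\t")
        clusters = [
            detect.GeneCluster(
                cluster_id=cid,
                member_gene_ids=list(sub["gene_id"]),
                representative_gene_id=sub["representative"].iloc[0],
            )
            for cid, sub in cl_df.groupby("cluster_id")
        ]
        annotations = {g.gene_id: g.cog_category for gm in data.genomes for g in gm.genes()}
        cluster_cogs = enrichment.assign_cluster_cog(clusters, annotations)
        strata = enrichment.hgt_clusters_by_stratum(rbh_events)
        if strata:
            enr = enrichment.cog_enrichment(cluster_cogs, strata, alpha=thr.bh_alpha)
            _save(enr, edir / "cog_enrichment.tsv", counts)
        hgt_gene_ids = {e.gene_a for e in rbh_events} | {e.gene_b for e in rbh_events}
        mge_rows = []
        all_genes = [g for gm in data.genomes for g in gm.genes()]
        for flag in MGE_FLAG_NAMES:
            odds, p, corrected = enrichment.mge_fold_enrichment(all_genes, hgt_gene_ids, flag)
            mge_rows.append(
                {"flag": flag, "odds_ratio": odds, "p": p, "haldane_corrected": corrected}
            )
        _save(pd.DataFrame(mge_rows), edir / "mge_enrichment.tsv", counts)
        _mark_stage(run_dir, "enrich", cfg_hash, counts)
    manifest["stages"]["enrich"] = {"done": config.stages["enrich"]}

    # ---- env_rf ----------------------------------------------------------
    if config.stages["env_rf"] and not _stage_done(run_dir, "env_rf", cfg_hash):
        rdir = run_dir / "env_rf"
        rdir.mkdir(exist_ok=True)
        counts = {}
        flags = {g: g in hgt_genomes for g in present.columns}
        response = cooccurrence.feature_prevalence(present, flags).dropna()
        env = data.samples.env.loc[response.index]
        kept, dropped = env_rf.dedupe_env(env, rho_threshold=thr.env_rho)
        _save(
            pd.DataFrame(dropped, columns=["dropped", "representative", "rho"]),
            rdir / "dropped_variables.tsv",
            counts,
        )
        env = env[kept]
        null = env_rf.importance_null_test(
            env,
            response,
            n_replicates=config.rf_null_replicates,
            n_trees=config.rf_trees,
            null_n_trees=config.rf_null_trees,
            seed=config.seed,
            alpha=thr.bh_alpha,
        )
        _save(null.reset_index(), rdir / "importance.tsv", counts)
        res, oob_r2, _imp = env_rf.fit_rf(env, response, n_trees=config.rf_trees, seed=config.seed)
        (rdir / "oob_r2.json").write_text(json.dumps({"oob_r2": oob_r2}) + "\n")
        _mark_stage(run_dir, "env_rf", cfg_hash, counts)
    manifest["stages"]["env_rf"] = {"done": config.stages["env_rf"]}

    (run_dir / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1) + "\n"
    )
    return manifest
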