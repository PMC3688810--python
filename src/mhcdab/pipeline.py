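"""End-to-end orchestration: simulate -> genotype -> phylo ->
selection/geneconv -> popgen, with one structured config, per-stage logging
and a manifest recording seeds, thresholds and input digests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import codonmodel, geneconv, genotyping, ng86, phylo, popgen, simulate, tags
from ._rng import spawn_seed
from .errors import ConfigurationError, DependencyError

log = logging.getLogger("mhcdab")

STAGES = ("simulate", "genotype", "phylo", "selection", "geneconv", "popgen")


@dataclass
class RunConfig:
    """All pipeline knobs in one place; round-trips through YAML."""
    seed: int = 1
    out_dir: str = "mhcdab-run"
    stages: list = field(default_factory=lambda: list(STAGES))
    # simulate
    n_per_lineage: int = 8
    divergence: float = 0.03
    populations: list = field(default_factory=lambda: [
        {"name": "pop1", "species": "A", "n": 12},
        {"name": "pop2", "species": "B", "n": 12},
    ])
    coverage: list = field(default_factory=lambda: [300, 1000])
    error_rate: float = 0.01
    chimera_fraction: float = 0.05
    microsat_loci: int = 25
    microsat_fst: float = 0.3
    n_hybrids: int = 0
    # genotype
    allow_mismatch: int = 0
    min_identity: float = 0.80
    mpaf_artefact_threshold: float = 0.05
    auto_accept_threshold: float = 0.50
    singleton_mpaf_floor: float = 0.20
    # phylo
    bootstrap_replicates: int = 1000
    distance_model: str = "jc"
    # selection
    ng_bootstrap: int = 1000
    site_models: list = field(default_factory=lambda: ["M0"])
    # geneconv
    geneconv_perms: int = 10000
    # popgen
    k_min: int = 1
    k_max: int = 4
    structure_runs: int = 2
    structure_sweeps: int = 1500
    structure_burnin: int = 500
    fst_bootstrap: int = 20000
    mantel_perms: int = 10000
    fst_min_n: int = 9

    def validate(self) -> None:
        if not 0 <= self.mpaf_artefact_threshold <= self.auto_accept_threshold <= 1:
            raise ConfigurationError("thresholds must satisfy 0 <= artefact "
                                     "<= auto-accept <= 1")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ConfigurationError(f"unknown config keys: {sorted(bad)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages in dependency order; returns the run
    directory.  Each downstream stage checks for its upstream outputs and
    raises :class:`DependencyError` naming the missing stage."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest = {"package_version": __version__, "seed": config.seed,
                "stages": {}, "inputs": {}}

    if "simulate" in config.stages:
        _stage_simulate(config, out)
        manifest["stages"]["simulate"] = "ok"
    if "genotype" in config.stages:
        _require(out, "simulate", "reads.fastq", "layout.csv", "metadata.tsv")
        _stage_genotype(config, out)
        manifest["stages"]["genotype"] = "ok"
    if "phylo" in config.stages:
        _require(out, "genotype", "catalog.fasta")
        _stage_phylo(config, out)
        manifest["stages"]["phylo"] = "ok"
    if "selection" in config.stages:
        _require(out, "phylo", "alleles.nwk")
        _stage_selection(config, out)
        manifest["stages"]["selection"] = "ok"
    if "geneconv" in config.stages:
        _require(out, "genotype", "catalog.fasta")
        _stage_geneconv(config, out)
        manifest["stages"]["geneconv"] = "ok"
    if "popgen" in config.stages:
        _require(out, "genotype", "presence.tsv")
        _stage_popgen(config, out)
        manifest["stages"]["popgen"] = "ok"

    for f in sorted(out.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest["inputs"][f.name] = _digest(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def _require(out: Path, stage: str, *files: str) -> None:
    missing = [f for f in files if not (out / f).exists()]
    if missing:
        raise DependencyError(f"stage {stage!r} outputs missing: {missing}; "
                              f"run the {stage!r} stage first")


def _stage_simulate(cfg: RunConfig, out: Path) -> None:
    seed = spawn_seed(cfg.seed, "stage-simulate")
    log.info("simulate: seed=%d n_per_lineage=%d error=%.3f chimera=%.3f",
             seed, cfg.n_per_lineage, cfg.error_rate, cfg.chimera_fraction)
    pool = simulate.generate_allele_pool(cfg.n_per_lineage,
                                         divergence=cfg.divergence, seed=seed)
    pool.to_fasta(out / "pool.fasta")
    genos = []
    meta_rows = []
    for pop in cfg.populations:
        g = simulate.simulate_genotypes(pool, pop["n"], species=pop["species"],
                                        population=pop["name"], seed=seed)
        genos.extend(g)
        for x in g:
            meta_rows.append({"specimen": x.specimen_id,
                              "population": x.population, "species": x.species})
    meta = pd.DataFrame(meta_rows)
    meta.to_csv(out / "metadata.tsv", sep="\t", index=False)
    cands = tags.enumerate_candidate_tags()
    tagset = tags.select_tag_set(cands, target_size=40, seed=seed)
    layout = tags.build_plate_layout(tagset, 12, 8,
                                     specimens=[g.specimen_id for g in genos])
    layout.to_csv(out / "layout.csv")
    rc = simulate.ReadSimConfig(coverage=tuple(cfg.coverage),
                                error_rate=cfg.error_rate,
                                chimera_fraction=cfg.chimera_fraction, seed=seed)
    reads, read_truth, amp_truth = simulate.simulate_read_set(genos, pool,
                                                              layout, rc)
    simulate.write_fastq(reads, out / "reads.fastq")
    read_truth.to_csv(out / "truth_reads.tsv", sep="\t", index=False)
    amp_truth.to_csv(out / "truth_amplicons.tsv", sep="\t", index=False)
    refs = pool.reference_sequences()
    with open(out / "references.fasta", "w") as fh:
        for marker, seq in refs.items():
            fh.write(f">{marker}\n{seq}\n")
    panel = simulate.simulate_microsat_panel(
        n_loci=cfg.microsat_loci, n_per_pop=tuple(p["n"] for p in cfg.populations[:2]),
        fst=cfg.microsat_fst, n_hybrids=cfg.n_hybrids, seed=seed)
    panel.genotypes.to_csv(out / "microsat.tsv", sep="\t", index=False)


def _read_fasta(path) -> dict:
    from Bio import SeqIO
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def _stage_genotype(cfg: RunConfig, out: Path) -> None:
    log.info("genotype: mpaf<%.2f artefact, >=%.2f auto-accept",
             cfg.mpaf_artefact_threshold, cfg.auto_accept_threshold)
    reads = simulate.read_fastq(out / "reads.fastq")
    layout = tags.PlateLayout.from_csv(out / "layout.csv")
    refs = _read_fasta(out / "references.fasta")
    meta = pd.read_csv(out / "metadata.tsv", sep="\t")
    res = genotyping.genotype_cohort(
        reads, layout, refs, meta, allow_mismatch=cfg.allow_mismatch,
        min_identity=cfg.min_identity,
        mpaf_artefact_threshold=cfg.mpaf_artefact_threshold,
        auto_accept_threshold=cfg.auto_accept_threshold,
        singleton_mpaf_floor=cfg.singleton_mpaf_floor)
    res.variant_table.to_tsv(out / "variants.tsv")
    res.catalog.to_fasta(out / "catalog.fasta")
    name_of = res.catalog.table.set_index("variant_id")["name"]
    calls = res.calls.assign(allele=res.calls["variant_id"].map(name_of))
    calls.to_csv(out / "calls.tsv", sep="\t", index=False)
    res.presence.to_tsv(out / "presence.tsv")
    summary = genotyping.summarize_population(res.presence, res.catalog)
    summary.to_csv(out / "population_summary.tsv", sep="\t", index=False)
    patterns = genotyping.lineage_pattern_frequencies(res.presence, res.catalog)
    patterns.to_csv(out / "expression_patterns.tsv", sep="\t", index=False)


def _catalog_seqs(out: Path) -> dict:
    return _read_fasta(out / "catalog.fasta")


def _stage_phylo(cfg: RunConfig, out: Path) -> None:
    seed = spawn_seed(cfg.seed, "stage-phylo")
    seqs = _catalog_seqs(out)
    log.info("phylo: %d alleles, %d bootstrap replicates", len(seqs),
             cfg.bootstrap_replicates)
    tree, support = phylo.bootstrap_support(
        seqs, replicates=cfg.bootstrap_replicates, seed=seed,
        model=cfg.distance_model)
    (out / "alleles.nwk").write_text(tree.newick(support=support) + "\n")


def _default_abs_mask(n_codons: int) -> list:
    return [p - 1 for p in ng86.BROWN_ABS_BETA1 if p <= n_codons]


def _stage_selection(cfg: RunConfig, out: Path) -> None:
    seed = spawn_seed(cfg.seed, "stage-selection")
    seqs = _catalog_seqs(out)
    n_codons = len(next(iter(seqs.values()))) // 3
    mask = _default_abs_mask(n_codons)
    rows = []
    for part in ("all", "abs", "non-abs"):
        r = ng86.partition_rates(seqs, partition=part, abs_mask=mask,
                                 bootstrap_reps=cfg.ng_bootstrap, seed=seed)
        rows.append({"partition": part, "dN": r.d_n, "dS": r.d_s,
                     "se_dN": r.se_d_n, "se_dS": r.se_d_s, "Z": r.z,
                     "p": r.p_value, "n_codons": r.n_codons})
    pd.DataFrame(rows).to_csv(out / "ng86.tsv", sep="\t", index=False)
    if cfg.site_models:
        tree_txt = (out / "alleles.nwk").read_text()
        # strip bootstrap labels for the codon model tree
        import re
        tree_txt = re.sub(r"\)(\d+):", "):", tree_txt)
        fits = {}
        fit_rows = []
        nulls = {"M3": "M0", "M2a": "M1a", "M8": "M7"}
        for model in cfg.site_models:
            m = codonmodel.CodonSiteModel(seqs, tree_txt, model=model)
            start = None
            if nulls.get(model) in fits:
                start = codonmodel.warm_start_from(fits[nulls[model]])
            fit = m.fit(seed=seed, start=start)
            fits[model] = fit
            fit_rows.append({"model": model, "loglik": fit.loglik,
                             "n_free": fit.n_free_omega,
                             "params": json.dumps({k: round(v, 4) for k, v in
                                                   fit.params.items()})})
        pd.DataFrame(fit_rows).to_csv(out / "site_models.tsv", sep="\t",
                                      index=False)
        lrt_rows = []
        for null, alt in (("M0", "M3"), ("M1a", "M2a"), ("M7", "M8")):
            if null in fits and alt in fits:
                stat, df, p = codonmodel.likelihood_ratio_test(fits[null],
                                                               fits[alt])
                lrt_rows.append({"null": null, "alt": alt, "stat": stat,
                                 "df": df, "p": p})
        if lrt_rows:
            pd.DataFrame(lrt_rows).to_csv(out / "lrt.tsv", sep="\t", index=False)
        for model in ("M2a", "M8"):
            if model in fits:
                beb = fits[model].beb()
                beb.to_frame().to_csv(out / f"beb_{model}.tsv", sep="\t",
                                      index=False)


def _stage_geneconv(cfg: RunConfig, out: Path) -> None:
    seed = spawn_seed(cfg.seed, "stage-geneconv")
    seqs = _catalog_seqs(out)
    res = geneconv.permutation_significance(seqs, n_perm=cfg.geneconv_perms,
                                            seed=seed)
    rows = [{"kind": h.kind, "seq1": h.seq1, "seq2": h.seq2 or "",
             "start": h.start, "end": h.end, "score": h.score,
             "sim_p": h.sim_p, "bc_ka_p": h.bc_ka_p}
            for h in res.inner + res.outer]
    df = pd.DataFrame(rows)
    df.to_csv(out / "geneconv.tsv", sep="\t", index=False)
    (out / "geneconv_global.json").write_text(json.dumps(
        {"global_inner_p": res.global_inner_p,
         "global_outer_p": res.global_outer_p, "n_perm": res.n_perm}))


def _stage_popgen(cfg: RunConfig, out: Path) -> None:
    seed = spawn_seed(cfg.seed, "stage-popgen")
    pres = pd.read_csv(out / "presence.tsv", sep="\t", index_col=0)
    pops = pres.pop("population")
    micro = pd.read_csv(out / "microsat.tsv", sep="\t")
    loci = sorted({c[:-2] for c in micro.columns if c.endswith("_1")})
    pop_sizes = pops.value_counts()
    eligible = [p for p in pop_sizes.index if pop_sizes[p] >= cfg.fst_min_n]
    if len(eligible) >= 2:
        fst_mhc = popgen.pairwise_fst(
            lambda pop_pair: popgen.fst_binary(
                pres, pops, pop_pair=pop_pair,
                bootstrap_reps=cfg.fst_bootstrap, seed=seed),
            eligible)
        fst_mhc.to_csv(out / "fst_mhc.tsv", sep="\t", index=False)
    ms_sizes = micro["population"].value_counts()
    ms_eligible = [p for p in ms_sizes.index if ms_sizes[p] >= cfg.fst_min_n]
    if len(ms_eligible) >= 2:
        fst_ms = popgen.pairwise_fst(
            lambda pop_pair: popgen.fst_microsat(
                micro, loci, pop_pair=pop_pair,
                bootstrap_reps=cfg.fst_bootstrap, seed=seed),
            ms_eligible)
        fst_ms.to_csv(out / "fst_microsat.tsv", sep="\t", index=False)
    # admixture clustering on the dominant MHC data
    runs_by_k = {}
    consensus = None
    for k in range(cfg.k_min, cfg.k_max + 1):
        runs = [popgen.admixture_infer(pres, k, n_sweeps=cfg.structure_sweeps,
                                       burn_in=cfg.structure_burnin,
                                       seed=spawn_seed(seed, f"run{k}-{r}"))
                for r in range(cfg.structure_runs)]
        runs_by_k[k] = [r.ln_prob for r in runs]
        if k == 2:
            consensus = popgen.align_replicate_runs(runs)
    if len(runs_by_k) >= 3:
        dk = popgen.evanno_delta_k(runs_by_k)
        dk.table.to_csv(out / "deltak.tsv", sep="\t", index=False)
    if consensus is not None:
        consensus.q.to_csv(out / "qmatrix_mhc_k2.tsv", sep="\t")
    # Mantel between the marker systems where >= 3 shared populations exist
    shared = [p for p in eligible if p in ms_eligible]
    if len(shared) >= 3:
        m1 = popgen.fst_to_distance_matrix(fst_mhc, shared)
        m2 = popgen.fst_to_distance_matrix(fst_ms, shared)
        r, p = popgen.mantel_test(m1, m2, shared, n_perm=cfg.mantel_perms,
                                  seed=seed)
        pd.DataFrame([{"r": r, "p": p, "n_pops": len(shared)}]).to_csv(
            out / "mantel.tsv", sep="\t", index=False)
    table, (r, p) = popgen.diversity_and_correlation(pres, pops, micro, loci,
                                                     floor=cfg.fst_min_n)
    table.to_csv(out / "diversity.tsv", sep="\t", index=False)
    (out / "diversity_correlation.json").write_text(
        json.dumps({"spearman_r": None if np.isnan(r) else r,
                    "p": None if np.isnan(p) else p}))


# ---------------------------------------------------------------------------
# Report

def generate_report(run_dir) -> str:
    """Human-readable markdown summary rendered from the stage TSVs only
    (no recomputation).  Missing stages appear as explicit gaps."""
    run_dir = Path(run_dir)
    if not run_dir.exists() or not any(run_dir.iterdir()):
        raise DependencyError(f"run directory {run_dir} is empty")
    parts = ["# mhcdab run report\n"]

    def section(title, fname, formatter=None):
        parts.append(f"## {title}\n")
        path = run_dir / fname
        if not path.exists():
            parts.append(f"_not available ({fname} missing)_\n")
            return
        df = pd.read_csv(path, sep="\t")
        parts.append("```\n"
                     + (formatter(df) if formatter else df.to_string(index=False))
                     + "\n```\n")

    section("Per-population allele summary", "population_summary.tsv")
    section("dN/dS by partition (NG86 + Jukes-Cantor, Z-test)", "ng86.tsv")
    section("Codon site models", "site_models.tsv")
    section("Likelihood-ratio tests", "lrt.tsv")
    section("Gene-conversion fragments", "geneconv.tsv")
    section("Pairwise F_st (MHC, dominant binary)", "fst_mhc.tsv")
    section("Pairwise F_st (microsatellites)", "fst_microsat.tsv")
    section("Evanno delta-K", "deltak.tsv")
    section("Diversity", "diversity.tsv")
    text = "\n".join(parts)
    (run_dir / "report.md").write_text(text)
    return text
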