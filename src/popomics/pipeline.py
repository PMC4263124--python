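"""Pipeline orchestration: simulate -> bin -> popsize -> express ->
variants -> nsi -> ecology, with a resolved-config copy and a manifest
(input/parameter digests, outputs, warnings) written next to the
results.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import binning, ecology, population, proteomics, synthetic, variants
from .errors import DependencyError, ParameterError
from .io import read_fasta, read_gff3, read_tsv, write_tsv, write_vcf
from .signatures import signature_matrix

logger = logging.getLogger(__name__)

STAGES = ("simulate", "bin", "popsize", "express", "variants", "nsi", "ecology")

_STAGE_DEFAULTS: dict[str, dict] = {
    "binning": dict(perplexity=30.0, k=None, init_means=None, min_posterior=0.5,
                    pseudocount=1.0, k_max=10, round2=False,
                    round2_min_length=1000, coverage_split=True, delta_bic=10.0),
    "popsize": dict(mode="relative"),
    "expression": dict(factor=50.0),
    "variants": dict(min_depth=10),
    "ecology": dict(depth=6359, reps=10, simpson_form="gini"),
}


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run."""

    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    community: dict = field(default_factory=dict)
    binning: dict = field(default_factory=dict)
    popsize: dict = field(default_factory=dict)
    expression: dict = field(default_factory=dict)
    variants: dict = field(default_factory=dict)
    ecology: dict = field(default_factory=dict)

    def __post_init__(self):
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ParameterError(f"unknown stages {unknown}")
        for name, defaults in _STAGE_DEFAULTS.items():
            block = dict(defaults)
            given = getattr(self, name)
            bad = set(given) - set(defaults)
            if bad:
                raise ParameterError(f"unknown keys in '{name}' block: {sorted(bad)}")
            block.update(given)
            setattr(self, name, block)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ParameterError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)

    def community_spec(self) -> synthetic.CommunitySpec:
        if not self.community:
            return synthetic.default_community(seed=self.seed)
        cfg = dict(self.community)
        pops = [synthetic.PopulationSpec(**p) for p in cfg.pop("populations")]
        cfg.setdefault("rng_seed", self.seed)
        return synthetic.CommunitySpec(populations=pops, **cfg)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    stages: list[dict] = field(default_factory=list)

    def record(self, name: str, params: dict, outputs: list[Path],
               warnings: int = 0) -> None:
        self.stages.append({
            "stage": name,
            "parameter_digest": hashlib.sha256(
                json.dumps(params, sort_keys=True, default=str).encode()
            ).hexdigest(),
            "outputs": {p.name: _sha256(p) for p in outputs},
            "warnings": warnings,
            "finished": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        })

    def write(self, path: Path) -> None:
        path.write_text(json.dumps({"stages": self.stages}, indent=2) + "\n")


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> RunManifest:
    """Execute the enabled stages in dependency order.

    Every stage writes its tables under ``out_dir``; the resolved config
    and a manifest with per-output SHA-256 digests are written alongside.
    A stage whose upstream outputs are missing raises
    :class:`DependencyError` naming the stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.resolved.yaml").write_text(yaml.safe_dump(asdict(config)))
    manifest = RunManifest()
    sim_dir = out / "sim"

    def _need(path: Path, stage: str) -> Path:
        if not path.exists():
            raise DependencyError(f"stage '{stage}' needs missing input {path}")
        return path

    if "simulate" in config.stages:
        spec = config.community_spec()
        bundle = synthetic.generate_community(spec)
        paths = synthetic.write_bundle(bundle, sim_dir)
        manifest.record("simulate", asdict(config)["community"] | {"seed": config.seed},
                        [Path(p) for p in paths])

    if "bin" in config.stages:
        bcfg = config.binning
        seqs = read_fasta(_need(sim_dir / "contigs.fasta", "bin"))
        ids, clr, meta = signature_matrix(seqs, pseudocount=bcfg["pseudocount"])
        binner = binning.CompositeGenomeBinner(
            n_components=bcfg["k"], init_means=bcfg["init_means"],
            k_max=bcfg["k_max"], perplexity=bcfg["perplexity"],
            min_posterior=bcfg["min_posterior"], random_state=config.seed)
        binner.fit(clr)
        assignments = binner.assignments(ids)
        if bcfg["round2"]:
            assignments = binning.iterate_binning(
                seqs, assignments, round2_min_length=bcfg["round2_min_length"],
                perplexity=bcfg["perplexity"], seed=config.seed,
                pseudocount=bcfg["pseudocount"])
        if bcfg["coverage_split"]:
            depth = read_tsv(_need(sim_dir / "depth.tsv", "bin"))
            dmap = depth.set_index("contig_id")["depth"]
            parts = []
            for cg, grp in assignments.groupby("cg_id"):
                if cg == binning.UNBINNED:
                    parts.append(grp[["contig_id", "cg_id"]])
                    continue
                split = binning.split_by_coverage(
                    grp["contig_id"].tolist(),
                    dmap.loc[grp["contig_id"]].to_numpy(),
                    cg_id=cg, delta_bic=bcfg["delta_bic"], seed=config.seed)
                parts.append(split)
            relabel = pd.concat(parts).set_index("contig_id")["cg_id"]
            assignments["cg_id"] = relabel.loc[assignments["contig_id"]].to_numpy()
        sig_path = out / "signatures.tsv"
        write_tsv(meta, sig_path, comment="length in bp; gc as fraction")
        emb_path = out / "embedding.tsv"
        write_tsv(pd.DataFrame({"contig_id": ids, "x": binner.embedding_[:, 0],
                                "y": binner.embedding_[:, 1]}), emb_path)
        bins_path = out / "bins.tsv"
        write_tsv(assignments, bins_path,
                  comment="posterior = max mixture responsibility")
        n_unbinned = int((assignments["cg_id"] == binning.UNBINNED).sum())
        manifest.record("bin", bcfg, [sig_path, emb_path, bins_path],
                        warnings=n_unbinned)

    if "popsize" in config.stages:
        bins = read_tsv(_need(out / "bins.tsv", "popsize"))
        counts = read_tsv(_need(sim_dir / "metag_counts.tsv", "popsize")).rename(
            columns={"id": "contig_id"})
        c_i, residual = binning.recruit_reads(bins, counts)
        lengths = counts.set_index("contig_id")["length"]
        lab = bins.set_index("contig_id")["cg_id"]
        l_i = lengths.groupby(lab.loc[lengths.index]).sum().drop(
            index=binning.UNBINNED, errors="ignore")
        depth = read_tsv(sim_dir / "depth.tsv").set_index("contig_id")["depth"]
        cov = depth.groupby(lab.loc[depth.index]).mean().drop(
            index=binning.UNBINNED, errors="ignore")
        profiles = pd.DataFrame({
            "cg_id": c_i.index, "l_i": l_i.loc[c_i.index].to_numpy(),
            "c_i": c_i.to_numpy(),
            "mean_coverage": cov.loc[c_i.index].to_numpy(),
        })
        profiles = population.population_size(profiles, mode=config.popsize["mode"])
        prof_path = out / "population_profile.tsv"
        write_tsv(profiles, prof_path,
                  comment=f"N_i mode = {config.popsize['mode']}; l_i in bp; "
                          f"residual (unbinned) reads = {residual}")
        manifest.record("popsize", config.popsize, [prof_path])

    if "express" in config.stages:
        profiles = read_tsv(_need(out / "population_profile.tsv", "express"))
        bins = read_tsv(_need(out / "bins.tsv", "express"))
        genes = read_gff3(_need(sim_dir / "genes.gff3", "express"))
        metat = read_tsv(_need(sim_dir / "metat_counts.tsv", "express")).rename(
            columns={"id": "gene_id"})
        genes["cg_id"] = genes["contig_id"].map(
            bins.set_index("contig_id")["cg_id"])
        n_i = profiles.set_index("cg_id")["N_i"]
        expr = population.expression_table(
            genes, metat, n_i, factor=config.expression["factor"])
        expr_path = out / "expression.tsv"
        write_tsv(expr[["gene_id", "cg_id", "length_nt", "metat_fpkm", "n_i",
                        "expressed", "threshold_factor"]], expr_path,
                  comment="FPKM = fragments per kb per 1e6 mapped; "
                          "expressed iff metat_fpkm >= factor * N_i")
        frac = expr.groupby("cg_id")["expressed"].agg(
            lambda s: population.expressed_fraction(s))
        frac_path = out / "expressed_fraction.tsv"
        write_tsv(frac.rename("expressed_pct").reset_index(), frac_path,
                  comment="percentage of genes expressed at the RNA level")
        manifest.record("express", config.expression, [expr_path, frac_path])

    if "variants" in config.stages:
        vcfs = sorted(sim_dir.glob("caller_*.vcf"))
        if len(vcfs) < 2:
            raise DependencyError("stage 'variants' needs >= 2 caller_*.vcf inputs")
        sets = [variants.parse_vcf(str(p), caller=p.stem) for p in vcfs]
        consensus = variants.intersect_callsets(sets)
        filtered = variants.depth_filter(consensus,
                                         min_depth=config.variants["min_depth"])
        profiles = read_tsv(_need(out / "population_profile.tsv", "variants"))
        bins = read_tsv(_need(out / "bins.tsv", "variants"))
        genes = read_gff3(_need(sim_dir / "genes.gff3", "variants"))
        contig_to_cg = dict(zip(bins["contig_id"], bins["cg_id"]))
        dens = variants.density_table(filtered, contig_to_cg, profiles)
        per_gene, intergenic = variants.per_gene_variant_counts(filtered, genes)
        vcf_path = out / "variants_intersection.vcf"
        write_vcf(pd.DataFrame(
            [(k.contig, k.pos, k.ref, k.alt, filtered.depth_g[k], filtered.depth_t[k])
             for k in sorted(filtered.variants)],
            columns=["contig", "pos", "ref", "alt", "dpg", "dpt"]), vcf_path)
        dens_path = out / "variant_density.tsv"
        write_tsv(dens, dens_path,
                  comment="snp_per_kb = variants per kb; normalized by N_i")
        pg_path = out / "per_gene_snps.tsv"
        write_tsv(per_gene, pg_path,
                  comment=f"intergenic variants = {intergenic}")
        manifest.record("variants", config.variants, [vcf_path, dens_path, pg_path])

    if "nsi" in config.stages:
        ev = read_tsv(_need(sim_dir / "protein_evidence.tsv", "nsi"))
        nsi = proteomics.nsi_table(ev)
        nsi_path = out / "nsi.tsv"
        write_tsv(nsi, nsi_path,
                  comment="nsi = si_raw / (length_aa * total si); dimensionless")
        manifest.record("nsi", {}, [nsi_path])

    if "ecology" in config.stages:
        ecfg = config.ecology
        ab = read_tsv(_need(sim_dir / "abundance.tsv", "ecology")).set_index("taxon")
        lipids = read_tsv(_need(sim_dir / "lipids.tsv", "ecology"))
        div = ecology.diversity_table(ab, depth=ecfg["depth"], reps=ecfg["reps"],
                                      seed=config.seed,
                                      simpson_form=ecfg["simpson_form"])
        ratios = ecology.accumulation_ratio(lipids)
        samples = div["sample"].tolist()
        corr_rows = []
        props = ab / ab.sum(axis=0)
        for taxon in ab.index:
            x = props.loc[taxon, samples].to_numpy()
            for comp, grp in ratios.groupby("compound"):
                y = grp.set_index("sample").loc[samples, "ratio"].to_numpy()
                corr_rows.append((taxon, comp, ecology.spearman(x, y)))
        div_path = out / "diversity.tsv"
        write_tsv(div, div_path,
                  comment=f"simpson form = {ecfg['simpson_form']}; "
                          f"rarefaction depth = {ecfg['depth']}, reps = {ecfg['reps']}")
        ratio_path = out / "ratios.tsv"
        write_tsv(ratios, ratio_path, comment="intracellular / extracellular")
        corr_path = out / "correlations.tsv"
        write_tsv(pd.DataFrame(corr_rows, columns=["taxon", "compound", "rho"]),
                  corr_path, comment="Spearman rho, average-tie ranks")
        manifest.record("ecology", ecfg, [div_path, ratio_path, corr_path])

    manifest.write(out / "manifest.json")
    return manifest
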