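"""Ground-truthed synthetic microbial community generator.

Emulates the statistical structure the population-resolved analysis
assumes: several populations with distinct G+C content and distinct
pentamer usage (so contigs separate in CLR signature space), skewed
relative abundances, a "generalist" population transcribing only a
fraction of its genes, population-specific SNP densities, and sparse
spectral evidence for a subset of expressed proteins.

Genomes are drawn from an order-2 Markov chain whose per-step G+C
probability equals the requested ``gc_fraction`` exactly; the split of
the G+C mass between G and C (and of the A+T mass between A and T) is
perturbed per di-nucleotide context with a strength set by
``signature_bias``, which gives each population its own expected
pentamer profile without disturbing its G+C content.

All randomness flows from one root seed through named
``numpy.random.SeedSequence`` substreams, so an identical
:class:`CommunitySpec` reproduces a byte-identical bundle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError

_BASES = "ACGT"


# ---------------------------------------------------------------------------
# specifications
# ---------------------------------------------------------------------------

@dataclass
class PopulationSpec:
    """Generative parameters of one community population."""

    pop_id: str
    genome_length: int = 2_000_000
    gc_fraction: float = 0.5
    signature_bias: float = 1.0
    relative_abundance: float = 0.5
    expressed_fraction: float = 0.9
    expression_dispersion: float = 0.3
    snp_per_kb: float = 1.0
    proteome_detect_fraction: float = 0.3

    def __post_init__(self):
        if not 0.0 < self.gc_fraction < 1.0:
            raise ParameterError(f"gc_fraction must be in (0,1), got {self.gc_fraction}")
        for name in ("expressed_fraction", "proteome_detect_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0,1], got {v}")
        if self.snp_per_kb < 0:
            raise ParameterError("snp_per_kb must be >= 0")


@dataclass
class CommunitySpec:
    """A community of populations plus sequencing-scale parameters."""

    populations: list[PopulationSpec]
    total_metag_reads: int = 2_000_000
    total_metat_reads: int = 2_000_000
    read_length: int = 150
    contig_length_law: dict = field(
        default_factory=lambda: {"name": "loguniform", "min": 1000, "max": 20000}
    )
    rng_seed: int = 0
    caller_names: tuple[str, ...] = ("mpileup", "unifiedgenotyper", "freebayes")
    caller_fp_rate: float = 0.02
    caller_dropout_rate: float = 0.02
    variant_depth_mean_g: float = 50.0
    variant_depth_mean_t: float = 50.0
    expression_level_sigma: float = 0.75
    # transcribed genes carry at least this baseline level, so "expressed"
    # in the ground truth means clearly detectable, not borderline
    expression_level_floor: float = 0.25

    def __post_init__(self):
        if len(self.populations) < 2:
            raise ParameterError("a community needs at least 2 populations")
        if self.total_metag_reads <= 0 or self.total_metat_reads <= 0:
            raise ParameterError("total read counts must be > 0")
        tot = sum(p.relative_abundance for p in self.populations)
        if abs(tot - 1.0) > 1e-9:
            raise ParameterError(f"relative abundances must sum to 1, got {tot}")


@dataclass
class GroundTruth:
    contig_to_pop: dict[str, str]
    gene_truth: pd.DataFrame       # gene_id, pop_id, expressed, level
    variant_truth: pd.DataFrame    # contig, pos, ref, alt, pop_id
    abundance_truth: dict[str, float]


@dataclass
class CommunityBundle:
    """Everything one simulated community produced, plus its ground truth."""

    spec: CommunitySpec
    sequences: dict[str, str]
    contigs: pd.DataFrame          # contig_id, pop_id, length
    genes: pd.DataFrame            # gene_id, contig_id, pop_id, start, end, strand, length_nt
    metag_counts: pd.DataFrame     # contig_id, length, count
    metat_counts: pd.DataFrame     # gene_id, length, count
    depth: pd.DataFrame            # contig_id, depth
    callsets: dict[str, pd.DataFrame]   # caller -> contig, pos, ref, alt, dpg, dpt
    protein_evidence: pd.DataFrame      # protein_id, length_aa, peptide_id, spectrum_id, intensity
    abundance: pd.DataFrame             # taxa x samples counts
    lipids: pd.DataFrame                # compound, sample, intracellular, extracellular
    truth: GroundTruth


# ---------------------------------------------------------------------------
# genome sequence
# ---------------------------------------------------------------------------

def _transition_cumulatives(gc: float, bias: float,
                            rng: np.random.Generator) -> list[tuple[float, float, float]]:
    """Per-context cumulative next-base probabilities (A,C,G order; T is rest).

    Each of the 16 di-nucleotide contexts splits the fixed G+C mass between
    G and C and the A+T mass between A and T with a logistic skew of scale
    ``bias``; per-step P(G)+P(C) is exactly ``gc`` in every context.
    """
    cums = []
    for _ctx in range(16):
        w_g = 1.0 / (1.0 + np.exp(-bias * rng.standard_normal()))
        w_a = 1.0 / (1.0 + np.exp(-bias * rng.standard_normal()))
        p_a = (1.0 - gc) * w_a
        p_c = gc * (1.0 - w_g)
        p_g = gc * w_g
        cums.append((p_a, p_a + p_c, p_a + p_c + p_g))
    return cums


def generate_genome(spec: PopulationSpec, seed: int) -> str:
    """One genome sequence from the population's order-2 Markov chain.

    The context-skew table is drawn from one substream and the chain from
    another, so the same spec and seed give the same sequence and two
    genomes of the same population share an expected pentamer profile.
    """
    if spec.genome_length < 10_000:
        raise ParameterError("genome_length must be >= 10000")
    ss = np.random.SeedSequence(seed).spawn(2)
    cums = _transition_cumulatives(spec.gc_fraction, spec.signature_bias,
                                   np.random.default_rng(ss[0]))
    rng = np.random.default_rng(ss[1])
    n = spec.genome_length
    gc = spec.gc_fraction
    marg = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = np.empty(n, dtype=np.uint8)
    first = rng.choice(4, size=2, p=marg)
    seq[0], seq[1] = first
    u = rng.random(n).tolist()
    ctx = int(first[0]) * 4 + int(first[1])
    out = seq  # local alias
    for i in range(2, n):
        c0, c1, c2 = cums[ctx]
        ui = u[i]
        if ui < c0:
            b = 0
        elif ui < c1:
            b = 1
        elif ui < c2:
            b = 2
        else:
            b = 3
        out[i] = b
        ctx = ((ctx & 3) << 2) | b
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[seq].tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# fragmentation
# ---------------------------------------------------------------------------

def fragment_into_contigs(genome: str, law: dict, seed: int) -> list[str]:
    """Tile a genome into non-overlapping contigs drawn from a length law.

    Supported laws: ``{"name": "fixed", "length": L}`` and
    ``{"name": "loguniform", "min": a, "max": b}``.  Every contig is at
    least the law minimum (>= 500) and the concatenation of the returned
    fragments reconstructs the genome exactly (a short terminal remainder
    is merged into the last contig).
    """
    name = law.get("name")
    if name == "fixed":
        lo = hi = int(law["length"])
    elif name == "loguniform":
        lo, hi = int(law["min"]), int(law["max"])
    else:
        raise ParameterError(f"unknown contig length law {name!r}")
    if lo < 500:
        raise ParameterError("contig length law minimum must be >= 500")
    if lo > hi:
        raise ParameterError("law minimum exceeds maximum")
    if len(genome) < lo:
        raise ParameterError("genome shorter than the law minimum")
    rng = np.random.default_rng(seed)
    cuts = [0]
    pos = 0
    n = len(genome)
    while pos < n:
        if name == "fixed":
            length = lo
        else:
            length = int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
        if n - pos - length < lo:     # remainder would violate the minimum
            length = n - pos
        pos += length
        cuts.append(pos)
    return [genome[a:b] for a, b in zip(cuts[:-1], cuts[1:])]


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

def _place_genes(contigs: pd.DataFrame, rng: np.random.Generator,
                 start_id: int = 1) -> pd.DataFrame:
    """Tile each contig with non-overlapping genes (1-based inclusive).

    Gene lengths are multiples of 3 between 300 and 1500 nt with short
    intergenic gaps; genes never span contig ends.
    """
    rows = []
    gid = start_id
    for contig_id, pop_id, length in contigs[["contig_id", "pop_id", "length"]].itertuples(index=False):
        pos = 1
        while True:
            gap = int(rng.integers(20, 120))
            glen = 3 * int(rng.integers(100, 501))
            start = pos + gap
            end = start + glen - 1
            if end > length:
                break
            rows.append((f"gene_{gid:06d}", contig_id, pop_id, start, end,
                         "+" if rng.random() < 0.5 else "-", glen))
            gid += 1
            pos = end + 1
    return pd.DataFrame(rows, columns=["gene_id", "contig_id", "pop_id",
                                       "start", "end", "strand", "length_nt"])


# ---------------------------------------------------------------------------
# read counts
# ---------------------------------------------------------------------------

def simulate_counts(community: CommunitySpec, contigs: pd.DataFrame,
                    genes: pd.DataFrame, gene_truth: pd.DataFrame,
                    seed: int) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Multinomial metaG per-contig counts, overdispersed metaT per-gene
    counts and per-contig depth.

    metaG read probability is proportional to relative_abundance x
    contig_length; metaT weight is abundance x true transcript level x a
    gamma multiplier of the population's dispersion for expressed genes and
    exactly zero otherwise.  Library totals are conserved exactly;
    depth = count x read_length / contig_length.
    """
    rng = np.random.default_rng(seed)
    pops = {p.pop_id: p for p in community.populations}
    for p in community.populations:
        if p.expressed_fraction > 0 and (genes["pop_id"] == p.pop_id).sum() == 0:
            raise ParameterError(f"population {p.pop_id} has no genes but "
                                 f"expressed_fraction > 0")

    ab = contigs["pop_id"].map(lambda q: pops[q].relative_abundance).to_numpy()
    w = ab * contigs["length"].to_numpy()
    cg_counts = rng.multinomial(community.total_metag_reads, w / w.sum())
    metag = pd.DataFrame({"contig_id": contigs["contig_id"],
                          "length": contigs["length"], "count": cg_counts})
    depth = pd.DataFrame({
        "contig_id": contigs["contig_id"],
        "depth": cg_counts * community.read_length / contigs["length"].to_numpy(),
    })

    gt = genes.merge(gene_truth[["gene_id", "expressed", "level"]], on="gene_id")
    disp = gt["pop_id"].map(lambda q: pops[q].expression_dispersion).to_numpy()
    gab = gt["pop_id"].map(lambda q: pops[q].relative_abundance).to_numpy()
    noise = np.ones(len(gt))
    over = disp > 0
    if over.any():
        noise[over] = rng.gamma(1.0 / disp[over], disp[over])
    wt = np.where(gt["expressed"].to_numpy(), gab * gt["level"].to_numpy() * noise, 0.0)
    if wt.sum() <= 0:
        raise ParameterError("no expressed gene in the community")
    ct_counts = rng.multinomial(community.total_metat_reads, wt / wt.sum())
    metat = pd.DataFrame({"gene_id": gt["gene_id"], "length": gt["length_nt"],
                          "count": ct_counts})
    return metag, metat, depth


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

def inject_variants(contigs: pd.DataFrame, sequences: dict[str, str],
                    spec: PopulationSpec, seed: int,
                    caller_names: tuple[str, ...] = ("a", "b"),
                    fp_rate: float = 0.0, dropout_rate: float = 0.0,
                    depth_mean_g: float = 50.0,
                    depth_mean_t: float = 50.0) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """True SNPs of one population plus noisy per-caller call sets.

    ``round(snp_per_kb x genome_length / 1000)`` variants are placed
    uniformly without collision over the population's contigs; each caller
    set is truth minus Bernoulli dropouts plus uniformly placed false
    positives, and every record carries metaG/metaT depths (Poisson around
    the configured means).
    """
    rng = np.random.default_rng(seed)
    sub = contigs[["contig_id", "length"]]
    genome_length = int(sub["length"].sum())
    n_true = int(round(spec.snp_per_kb * genome_length / 1000))
    if n_true > genome_length:
        raise ParameterError("cannot place variants without collision")
    offsets = np.concatenate([[0], np.cumsum(sub["length"].to_numpy())])
    cid = sub["contig_id"].to_numpy()

    def _locate(gpos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        idx = np.searchsorted(offsets, gpos, side="right") - 1
        return cid[idx], (gpos - offsets[idx] + 1).astype(int)  # 1-based

    gpos = np.sort(rng.choice(genome_length, size=n_true, replace=False))
    contig, pos = _locate(gpos)
    ref = np.array([sequences[c][p - 1] for c, p in zip(contig, pos)])
    other = {b: [x for x in _BASES if x != b] for b in _BASES}
    alt = np.array([other[r][rng.integers(3)] for r in ref])
    truth = pd.DataFrame({"contig": contig, "pos": pos, "ref": ref, "alt": alt,
                          "pop_id": spec.pop_id})

    taken = set(gpos.tolist())
    callsets: dict[str, pd.DataFrame] = {}
    for caller in caller_names:
        keep = rng.random(n_true) >= dropout_rate
        df = truth.loc[keep, ["contig", "pos", "ref", "alt"]].copy()
        n_fp = int(round(fp_rate * n_true))
        if n_fp:
            fp_pos = []
            while len(fp_pos) < n_fp:
                cand = int(rng.integers(genome_length))
                if cand not in taken:
                    fp_pos.append(cand)
            fp_pos = np.array(sorted(fp_pos))
            fc, fpp = _locate(fp_pos)
            fref = np.array([sequences[c][p - 1] for c, p in zip(fc, fpp)])
            falt = np.array([other[r][rng.integers(3)] for r in fref])
            df = pd.concat([df, pd.DataFrame({"contig": fc, "pos": fpp,
                                              "ref": fref, "alt": falt})],
                           ignore_index=True)
        df["dpg"] = rng.poisson(depth_mean_g, size=len(df))
        df["dpt"] = rng.poisson(depth_mean_t, size=len(df))
        callsets[caller] = df.sort_values(["contig", "pos"]).reset_index(drop=True)
    return truth, callsets


# ---------------------------------------------------------------------------
# proteomic evidence
# ---------------------------------------------------------------------------

def simulate_spectra(expressed_genes: pd.DataFrame, spec: PopulationSpec,
                     seed: int) -> pd.DataFrame:
    """Sparse spectral evidence for a fraction of expressed proteins.

    ``expressed_genes`` needs columns gene_id, length_nt and level.  For a
    ``proteome_detect_fraction`` subset, one or more peptides each carry one
    or more spectra with a positive summed fragment-ion intensity scaled by
    the transcript level.  Undetected proteins are absent from the table.
    """
    rng = np.random.default_rng(seed)
    n = len(expressed_genes)
    n_detect = int(round(spec.proteome_detect_fraction * n))
    rows = []
    if n_detect:
        chosen = expressed_genes.iloc[
            rng.permutation(n)[:n_detect]
        ]
        for gene_id, length_nt, level in chosen[["gene_id", "length_nt", "level"]].itertuples(index=False):
            length_aa = int(length_nt) // 3
            for p in range(1 + rng.poisson(2)):
                pep = f"{gene_id}_p{p + 1}"
                for s in range(1 + rng.poisson(1)):
                    intensity = float(level * rng.lognormal(12.0, 1.0))
                    rows.append((gene_id, length_aa, pep, f"{pep}_s{s + 1}", intensity))
    return pd.DataFrame(rows, columns=["protein_id", "length_aa", "peptide_id",
                                       "spectrum_id", "intensity"])


# ---------------------------------------------------------------------------
# ecology-layer tables
# ---------------------------------------------------------------------------

#: the quantified long-chain fatty acids (external calibration standards).
LIPID_COMPOUNDS = (
    "hexanoic", "octanoic", "decanoic", "dodecanoic", "tetradecanoic",
    "palmitoleic", "hexadecanoic", "linoleic", "oleic", "linolenic",
    "octadecanoic", "eicosanoic", "docosanoic", "tetracosanoic",
)


def simulate_ecology_tables(spec: CommunitySpec, seed: int, n_samples: int = 4,
                            reads_per_sample: int = 10_000
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Taxon abundance matrix and lipid quantification table.

    Each sample's taxon counts are a multinomial draw around the
    population abundances (Dirichlet-jittered so samples differ); the
    lipid table carries intracellular and extracellular concentrations per
    compound and sample, with intracellular accumulation correlated with
    the first (lipid-accumulating) population's abundance.
    """
    rng = np.random.default_rng(seed)
    base = np.array([p.relative_abundance for p in spec.populations])
    taxa = [p.pop_id for p in spec.populations]
    cols = {}
    sample_ab = []
    for s in range(n_samples):
        props = rng.dirichlet(base * 50.0)
        cols[f"sample{s + 1}"] = rng.multinomial(reads_per_sample, props)
        sample_ab.append(props[0])
    abundance = pd.DataFrame(cols, index=pd.Index(taxa, name="taxon"))

    rows = []
    for s, ab0 in enumerate(sample_ab):
        for comp in LIPID_COMPOUNDS:
            extra = float(rng.lognormal(2.0, 0.4))
            ratio = float(np.exp(1.5 * ab0) * rng.lognormal(0.0, 0.25))
            rows.append((comp, f"sample{s + 1}", extra * ratio, extra))
    lipids = pd.DataFrame(rows, columns=["compound", "sample",
                                         "intracellular", "extracellular"])
    return abundance, lipids


# ---------------------------------------------------------------------------
# whole-community orchestration
# ---------------------------------------------------------------------------

def generate_community(spec: CommunitySpec) -> CommunityBundle:
    """Generate the full multi-omic bundle for a community specification."""
    root = np.random.SeedSequence(spec.rng_seed)
    streams = {name: s for name, s in zip(
        ("genomes", "fragments", "genes", "truth", "counts", "variants", "spectra"),
        root.spawn(7),
    )}

    # genomes and contigs
    seq_rows = []
    sequences: dict[str, str] = {}
    contig_idx = 1
    gseeds = streams["genomes"].spawn(len(spec.populations))
    fseeds = streams["fragments"].spawn(len(spec.populations))
    for p, gs, fs in zip(spec.populations, gseeds, fseeds):
        genome = generate_genome(p, seed=gs.generate_state(1)[0] % (2 ** 31))
        frags = fragment_into_contigs(genome, spec.contig_length_law,
                                      seed=fs.generate_state(1)[0] % (2 ** 31))
        for frag in frags:
            cid = f"contig_{contig_idx:05d}"
            sequences[cid] = frag
            seq_rows.append((cid, p.pop_id, len(frag)))
            contig_idx += 1
    contigs = pd.DataFrame(seq_rows, columns=["contig_id", "pop_id", "length"])

    genes = _place_genes(contigs, np.random.default_rng(streams["genes"]))

    # expression ground truth: exactly round(frac * n) expressed genes per pop
    rng_truth = np.random.default_rng(streams["truth"])
    truth_parts = []
    for p in spec.populations:
        sub = genes[genes["pop_id"] == p.pop_id]
        n = len(sub)
        n_expr = int(round(p.expressed_fraction * n))
        order = rng_truth.permutation(n)
        expressed = np.zeros(n, dtype=bool)
        expressed[order[:n_expr]] = True
        level = np.where(
            expressed,
            spec.expression_level_floor
            + rng_truth.lognormal(0.0, spec.expression_level_sigma, n),
            0.0)
        truth_parts.append(pd.DataFrame({
            "gene_id": sub["gene_id"].to_numpy(), "pop_id": p.pop_id,
            "expressed": expressed, "level": level,
        }))
    gene_truth = pd.concat(truth_parts, ignore_index=True)

    metag, metat, depth = simulate_counts(
        spec, contigs, genes, gene_truth,
        seed=streams["counts"].generate_state(1)[0] % (2 ** 31))

    # variants
    vseeds = streams["variants"].spawn(len(spec.populations))
    truth_v, merged_callsets = [], {c: [] for c in spec.caller_names}
    for p, vs in zip(spec.populations, vseeds):
        tv, cs = inject_variants(
            contigs[contigs["pop_id"] == p.pop_id], sequences, p,
            seed=vs.generate_state(1)[0] % (2 ** 31),
            caller_names=spec.caller_names,
            fp_rate=spec.caller_fp_rate, dropout_rate=spec.caller_dropout_rate,
            depth_mean_g=spec.variant_depth_mean_g,
            depth_mean_t=spec.variant_depth_mean_t)
        truth_v.append(tv)
        for c in spec.caller_names:
            merged_callsets[c].append(cs[c])
    variant_truth = pd.concat(truth_v, ignore_index=True)
    callsets = {c: pd.concat(v, ignore_index=True) for c, v in merged_callsets.items()}

    # proteomics
    sseeds = streams["spectra"].spawn(len(spec.populations))
    ev_parts = []
    gt_merged = genes.merge(gene_truth[["gene_id", "expressed", "level"]], on="gene_id")
    for p, ss in zip(spec.populations, sseeds):
        expressed = gt_merged[(gt_merged["pop_id"] == p.pop_id) & gt_merged["expressed"]]
        ev_parts.append(simulate_spectra(expressed, p,
                                         seed=ss.generate_state(1)[0] % (2 ** 31)))
    non_empty = [e for e in ev_parts if len(e)]
    protein_evidence = (pd.concat(non_empty, ignore_index=True)
                        if non_empty else ev_parts[0])

    abundance, lipids = simulate_ecology_tables(
        spec, seed=streams["spectra"].spawn(1)[0].generate_state(1)[0] % (2 ** 31))

    truth = GroundTruth(
        contig_to_pop=dict(zip(contigs["contig_id"], contigs["pop_id"])),
        gene_truth=gene_truth,
        variant_truth=variant_truth,
        abundance_truth={p.pop_id: p.relative_abundance for p in spec.populations},
    )
    return CommunityBundle(spec=spec, sequences=sequences, contigs=contigs,
                           genes=genes, metag_counts=metag, metat_counts=metat,
                           depth=depth, callsets=callsets,
                           protein_evidence=protein_evidence,
                           abundance=abundance, lipids=lipids, truth=truth)


def write_bundle(bundle: CommunityBundle, out_dir) -> list[str]:
    """Write the bundle to disk in the pipeline's on-disk formats.

    Emits contigs.fasta, genes.gff3, metag_counts.tsv, metat_counts.tsv,
    depth.tsv, caller_<name>.vcf, protein_evidence.tsv, abundance.tsv,
    lipids.tsv and the truth/ tables; returns the written paths.
    """
    from pathlib import Path

    from .io import write_fasta, write_gff3, write_tsv, write_vcf

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    written = []

    def _w(path, fn):
        fn(path)
        written.append(str(path))

    _w(out / "contigs.fasta", lambda p: write_fasta(bundle.sequences, p))
    _w(out / "genes.gff3", lambda p: write_gff3(bundle.genes, p))
    _w(out / "metag_counts.tsv",
       lambda p: write_tsv(bundle.metag_counts.rename(columns={"contig_id": "id"}),
                           p, comment="metagenomic reads per contig; length in bp"))
    _w(out / "metat_counts.tsv",
       lambda p: write_tsv(bundle.metat_counts.rename(columns={"gene_id": "id"}),
                           p, comment="metatranscriptomic fragments per gene; length in bp"))
    _w(out / "depth.tsv",
       lambda p: write_tsv(bundle.depth, p, comment="fold coverage per contig"))
    for caller, df in bundle.callsets.items():
        _w(out / f"caller_{caller}.vcf",
           lambda p, df=df: write_vcf(df, p, contigs=bundle.contigs))
    _w(out / "protein_evidence.tsv",
       lambda p: write_tsv(bundle.protein_evidence, p,
                           comment="summed fragment-ion intensity per spectrum"))
    _w(out / "abundance.tsv",
       lambda p: write_tsv(bundle.abundance.reset_index(), p,
                           comment="taxon read counts per sample"))
    _w(out / "lipids.tsv",
       lambda p: write_tsv(bundle.lipids, p,
                           comment="long-chain fatty acid concentrations"))
    _w(out / "truth" / "contig_to_pop.tsv",
       lambda p: write_tsv(pd.DataFrame(
           {"contig_id": list(bundle.truth.contig_to_pop),
            "pop_id": list(bundle.truth.contig_to_pop.values())}), p))
    _w(out / "truth" / "gene_truth.tsv",
       lambda p: write_tsv(bundle.truth.gene_truth, p))
    _w(out / "truth" / "variant_truth.tsv",
       lambda p: write_tsv(bundle.truth.variant_truth, p))
    _w(out / "truth" / "abundance_truth.tsv",
       lambda p: write_tsv(pd.DataFrame(
           {"pop_id": list(bundle.truth.abundance_truth),
            "relative_abundance": list(bundle.truth.abundance_truth.values())}), p))
    return written


# ---------------------------------------------------------------------------
# documented default communities
# ---------------------------------------------------------------------------

def default_community(seed: int = 0, genome_length: int = 2_000_000) -> CommunitySpec:
    """The package's default five-population community.

    G+C spans 0.35-0.65, abundances are skewed, the most abundant
    population is a generalist transcribing 45% of its genes while a
    high-expression specialist-like population transcribes 93%, and SNP
    densities differ by an order of magnitude.
    """
    gcs = [0.35, 0.425, 0.50, 0.575, 0.65]
    abundances = [0.40, 0.25, 0.15, 0.12, 0.08]
    expressed = [0.45, 0.93, 0.85, 0.90, 0.95]
    snps = [0.5, 5.0, 2.0, 1.0, 3.0]
    pops = [
        PopulationSpec(pop_id=f"pop{i + 1}", genome_length=genome_length,
                       gc_fraction=g, signature_bias=1.0, relative_abundance=a,
                       expressed_fraction=e, snp_per_kb=s)
        for i, (g, a, e, s) in enumerate(zip(gcs, abundances, expressed, snps))
    ]
    return CommunitySpec(populations=pops, rng_seed=seed)


def two_population_community(seed: int = 0,
                             abundances: tuple[float, float] = (0.5, 0.5),
                             snp_per_kb: tuple[float, float] = (5.0, 0.5),
                             genome_length: int = 1_000_000,
                             **kwargs) -> CommunitySpec:
    """A small two-population community (equal sizes by default), used for
    variant-density and coverage-splitting studies."""
    pops = [
        PopulationSpec(pop_id="popA", genome_length=genome_length, gc_fraction=0.45,
                       relative_abundance=abundances[0], expressed_fraction=0.9,
                       snp_per_kb=snp_per_kb[0]),
        PopulationSpec(pop_id="popB", genome_length=genome_length, gc_fraction=0.55,
                       relative_abundance=abundances[1], expressed_fraction=0.9,
                       snp_per_kb=snp_per_kb[1]),
    ]
    return CommunitySpec(populations=pops, rng_seed=seed, **kwargs)
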