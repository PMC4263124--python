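# popomics

Population-resolved multi-omic analysis of microbial communities.

Shotgun sequencing of a mixed microbial community — for example the
oleaginous, lipid-accumulating biofilms that float on wastewater
treatment tanks — yields contigs, transcripts, variants and spectra from
*all* member populations at once. To say anything about the ecology of a
single population (is it a generalist that transcribes only a sliver of
its genome? does it accumulate genetic variation?), the community data
must first be deconvoluted into population-level composite genomes and
every downstream measurement put on a population-normalized scale.
`popomics` implements that workflow as a tested, reusable library with a
CLI, together with a ground-truthed synthetic community generator that
makes the whole chain verifiable end to end.

## What it computes

**Composite-genome binning.** Each contig is profiled by its canonical
pentanucleotide counts (512 dimensions after merging reverse
complements), mapped through the centred log-ratio transform,
projected to 2-D with Barnes–Hut t-SNE, and clustered by
expectation–maximisation on a Gaussian mixture (user-initialised means
or automatic k-means++/BIC mode; diagonal small-positive covariance
initialisation; covariance floor). Bins can be refined by a second
within-bin pass over contigs ≥ 1 kb and split by read-depth bimodality
(1- vs 2-component mixture on log₁₀ depth with ΔBIC, Ashman-D and
minimum-weight guards).

**Relative population size.** For composite genome *i* with length
*l*ᵢ and mapped metagenomic reads *c*ᵢ,

    N_i = (c_i / l_i) / Σ_j (c_j / l_j)

an RPKM-analogous, length-corrected relative abundance (Σ Nᵢ = 1; an
unnormalized `rpkm_like` mode is available).

**Population-normalized expression.** Per-gene FPKM
(`count · 10⁹ / (length · total_mapped)`); a gene is *expressed* iff its
metatranscriptomic FPKM ≥ 50 × Nᵢ, so abundant and rare populations are
judged on the same footing.

**Variant integration.** SNP call sets from several callers are reduced
to exact (contig, pos, ref, alt) keys, intersected, filtered on joint
metagenomic/metatranscriptomic depth (both ≥ 10), and summarised as
SNPs · kb⁻¹ / Nᵢ per population.

**Proteomics.** The normalized spectral index
`NSI_p = SI_p / (length_p · Σ_q SI_q)` where SI sums fragment-ion
intensity over a protein's peptides and spectra; Σ NSIₚ·lengthₚ = 1 by
construction, and log₂ NSI is reported for ratio comparisons.

**Ecology.** Rarefied Gini–Simpson diversity and Pielou evenness
(subsampling without replacement, 6,359 reads × 10 replicates by
default), lipid intracellular/extracellular accumulation ratios, and
taxon–lipid Spearman correlations.

## Worked example

```python
import pandas as pd
import popomics as pm
from popomics import population as pop
from popomics.signatures import signature_matrix

bundle = pm.generate_community(pm.default_community(seed=1))
ids, clr, meta = signature_matrix(bundle.sequences)
binner = pm.CompositeGenomeBinner(n_components=5, random_state=1).fit(clr)

assignments = binner.assignments(ids)
c_i, residual = pm.recruit_reads(assignments, bundle.metag_counts)
lab = assignments.set_index("contig_id")["cg_id"]
l_i = (bundle.metag_counts.set_index("contig_id")["length"]
       .groupby(lab.loc[bundle.metag_counts["contig_id"]].to_numpy()).sum())
prof = pop.population_size(pd.DataFrame(
    {"cg_id": c_i.index, "l_i": l_i.loc[c_i.index].to_numpy(),
     "c_i": c_i.to_numpy()}))

genes = bundle.genes.assign(cg_id=bundle.genes["contig_id"].map(lab))
expr = pop.expression_table(genes, bundle.metat_counts,
                            prof.set_index("cg_id")["N_i"])
prof["expressed_pct"] = (expr.groupby("cg_id")["expressed"]
                         .agg(pop.expressed_fraction)
                         .loc[prof["cg_id"]].to_numpy())
print(prof.round(4).to_string(index=False))
```

prints

```
cg_id     l_i    c_i    N_i  expressed_pct
  CG1 2000000 299755 0.1499        84.4845
  CG2 2000000 801291 0.4006        44.9170
  CG3 2000000 500211 0.2501        92.5965
  CG4 2000000 158991 0.0795        94.3785
  CG5 2000000 239752 0.1199        89.5639
```

Five composite genomes are recovered from the 1,601 simulated contigs
(adjusted Rand index 1.0 against the planted populations). `N_i` is each
population's length-normalized share of metagenomic reads; the dominant
bin CG2 (Nᵢ ≈ 0.40) is the planted *generalist*: under the ≥ 50 × Nᵢ
rule only ~45 % of its genes are expressed, while the other populations
express 84–94 % of theirs — the contrast between a dominant,
tightly-regulated generalist and high-expression specialist-like
populations that the population-normalized threshold is designed to
expose.

The same chain is available from the shell:

```sh
popomics simulate --out sim --seed 1
popomics bin --contigs sim/contigs.fasta --k 5 --seed 1 --out binned
popomics run-all --out full_run --seed 1
```

## Layout

- `src/popomics/synthetic.py` — ground-truthed community generator
- `src/popomics/signatures.py`, `binning.py` — signatures, embedding, EM
  mixture, `CompositeGenomeBinner`
- `src/popomics/population.py` — N_i, FPKM, expression calls, COG
  profiles, completeness, reciprocal-best-hit AAI
- `src/popomics/variants.py` — VCF parsing, intersection, depth filter,
  densities
- `src/popomics/proteomics.py` — spectral index / NSI
- `src/popomics/ecology.py` — rarefaction, diversity, evenness,
  correlations
- `src/popomics/pipeline.py`, `cli.py`, `io.py` — orchestration, CLI,
  readers/writers
- `docs/methods.md` — models, parameter choices and limitations
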