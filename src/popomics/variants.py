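"""Multi-caller SNP integration and population-normalized variant density.

Call sets from independent variant callers are normalized to exact
(contig, position, ref, alt) keys, intersected (a variant must be seen
by every caller), filtered on joint metagenomic/metatranscriptomic read
depth (both >= 10 by default), and summarised per composite genome as
SNPs per kilobase divided by the relative population size N_i.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import pandas as pd
from intervaltree import IntervalTree

from .errors import DomainError, InputError, ParameterError

_SNP_BASES = frozenset("ACGT")


class VariantKey(NamedTuple):
    """Exact identity of a biallelic SNP."""

    contig: str
    pos: int          # 1-based
    ref: str
    alt: str


def make_key(contig: str, pos: int, ref: str, alt: str) -> VariantKey:
    ref, alt = ref.upper(), alt.upper()
    if pos < 1:
        raise InputError(f"position must be >= 1, got {pos}")
    if ref not in _SNP_BASES or alt not in _SNP_BASES or ref == alt:
        raise InputError(f"not a SNP: {ref}>{alt}")
    return VariantKey(contig, int(pos), ref, alt)


@dataclass
class CallSet:
    """One caller's SNPs with per-library depths."""

    caller: str
    variants: set[VariantKey] = field(default_factory=set)
    depth_g: dict[VariantKey, int] = field(default_factory=dict)
    depth_t: dict[VariantKey, int] = field(default_factory=dict)
    n_skipped: int = 0     # non-SNP records dropped during parsing

    def add(self, key: VariantKey, depth_g: int, depth_t: int) -> None:
        if depth_g < 0 or depth_t < 0:
            raise InputError("depths must be >= 0")
        self.variants.add(key)
        self.depth_g[key] = int(depth_g)
        self.depth_t[key] = int(depth_t)


def callset_from_frame(caller: str, df: pd.DataFrame) -> CallSet:
    """Build a CallSet from a (contig, pos, ref, alt, dpg, dpt) frame."""
    cs = CallSet(caller=caller)
    for contig, pos, ref, alt, dpg, dpt in df[
        ["contig", "pos", "ref", "alt", "dpg", "dpt"]
    ].itertuples(index=False):
        cs.add(make_key(contig, pos, ref, alt), dpg, dpt)
    return cs


def parse_vcf(path: str, caller: str | None = None,
              depth_g_field: str = "DPG", depth_t_field: str = "DPT",
              missing_depth: str = "zero") -> CallSet:
    """Read a VCF 4.2 file into a CallSet.

    Multiallelic records are decomposed into one key per ALT allele;
    non-SNP alleles (indels, symbolic) are skipped and counted in
    ``n_skipped``.  Depths come from the two INFO fields; a missing field
    is treated as 0 (``missing_depth="zero"``) or drops the record
    (``"skip"``).
    """
    from cyvcf2 import VCF

    if missing_depth not in ("zero", "skip"):
        raise ParameterError("missing_depth must be 'zero' or 'skip'")
    cs = CallSet(caller=caller or str(path))
    for rec in VCF(str(path)):
        ref = str(rec.REF).upper()
        dg = rec.INFO.get(depth_g_field)
        dt = rec.INFO.get(depth_t_field)
        if (dg is None or dt is None) and missing_depth == "skip":
            cs.n_skipped += len(rec.ALT)
            continue
        for alt in rec.ALT:
            alt = str(alt).upper()
            if len(ref) != 1 or len(alt) != 1 or ref not in _SNP_BASES \
                    or alt not in _SNP_BASES or ref == alt:
                cs.n_skipped += 1
                continue
            cs.add(VariantKey(rec.CHROM, rec.POS, ref, alt),
                   int(dg or 0), int(dt or 0))
    return cs


def intersect_callsets(callsets: Iterable[CallSet]) -> CallSet:
    """Consensus of several callers: keep variants present in every set.

    Per-library depths of a retained variant are the minimum over callers
    (the conservative choice).  At least two call sets are required.
    """
    callsets = list(callsets)
    if len(callsets) < 2:
        raise ParameterError("need at least 2 call sets to intersect")
    keys = set.intersection(*(cs.variants for cs in callsets))
    out = CallSet(caller="+".join(cs.caller for cs in callsets))
    for k in keys:
        out.add(k, min(cs.depth_g[k] for cs in callsets),
                min(cs.depth_t[k] for cs in callsets))
    return out


def depth_filter(callset: CallSet, min_depth: int = 10) -> CallSet:
    """Keep variants with metaG depth >= min_depth AND metaT depth >=
    min_depth (boundary inclusive)."""
    out = CallSet(caller=callset.caller)
    for k in callset.variants:
        if callset.depth_g[k] >= min_depth and callset.depth_t[k] >= min_depth:
            out.add(k, callset.depth_g[k], callset.depth_t[k])
    return out


@dataclass
class DensitySummary:
    cg_id: str
    v_i: int
    snp_per_kb: float
    normalized_density: float


def variant_density(v_i: int, l_i: int, n_i: float,
                    cg_id: str = "CG") -> DensitySummary:
    """SNPs per kilobase of a composite genome, normalized by its relative
    population size N_i."""
    if l_i <= 0:
        raise DomainError("CG length must be positive")
    if n_i <= 0:
        raise DomainError("N_i must be positive to normalize")
    if v_i < 0:
        raise DomainError("variant count must be >= 0")
    per_kb = v_i / (l_i / 1000.0)
    return DensitySummary(cg_id=cg_id, v_i=int(v_i), snp_per_kb=per_kb,
                          normalized_density=per_kb / n_i)


def density_table(callset: CallSet, contig_to_cg: dict[str, str],
                  profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-CG density summaries for a filtered consensus call set.

    ``profiles`` needs cg_id, l_i and N_i columns (see
    :func:`popomics.population.population_size`).  Variants on contigs
    without a CG are ignored.
    """
    counts: dict[str, int] = {}
    for k in callset.variants:
        cg = contig_to_cg.get(k.contig)
        if cg is not None:
            counts[cg] = counts.get(cg, 0) + 1
    rows = []
    for cg_id, l_i, n_i in profiles[["cg_id", "l_i", "N_i"]].itertuples(index=False):
        d = variant_density(counts.get(cg_id, 0), int(l_i), float(n_i), cg_id=cg_id)
        rows.append((d.cg_id, d.v_i, d.snp_per_kb, d.normalized_density))
    return pd.DataFrame(rows, columns=["cg_id", "v_i", "snp_per_kb",
                                       "normalized_density"])


def per_gene_variant_counts(callset: CallSet,
                            genes: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Count variants per gene (1-based inclusive intervals).

    A variant increments every gene whose interval contains its position
    (overlapping genes all count); variants inside no gene are returned as
    the intergenic count.
    """
    bad = genes[genes["end"] < genes["start"]]
    if len(bad):
        raise InputError(f"gene {bad.iloc[0]['gene_id']} has end < start")
    trees: dict[str, IntervalTree] = {}
    for gene_id, contig_id, start, end in genes[
        ["gene_id", "contig_id", "start", "end"]
    ].itertuples(index=False):
        trees.setdefault(contig_id, IntervalTree()).addi(start, end + 1, gene_id)
    counts = {g: 0 for g in genes["gene_id"]}
    intergenic = 0
    for k in callset.variants:
        tree = trees.get(k.contig)
        hits = tree[k.pos] if tree is not None else ()
        if hits:
            for iv in hits:
                counts[iv.data] += 1
        else:
            intergenic += 1
    table = pd.DataFrame({"gene_id": list(counts), "n_variants": list(counts.values())})
    return table.sort_values("gene_id").reset_index(drop=True), intergenic
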