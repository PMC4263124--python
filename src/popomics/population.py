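"""Population-level metrics for composite genomes (CGs).

The central quantity is the relative population size N_i of a composite
genome: its mapped metagenomic read count c_i is normalized by its
length l_i and expressed as a share of the community,

    N_i = (c_i / l_i) / sum_j (c_j / l_j),

a dimensionless, length-corrected relative abundance (an RPKM-analogous
measure; an unnormalized "rpkm_like" scale, 1e9 * c_i / (C * l_i), is
provided for sensitivity analysis).  N_i drives the expression call: a
gene counts as expressed when its metatranscriptomic FPKM is at least
``factor`` (default 50) times the N_i of its population, which puts
abundant and rare populations on a comparable footing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import DomainError, InputError, ParameterError

#: COG functional category alphabet (single letters plus the three
#: aggregate classes used for multi-category and unassigned genes).
COG_LETTERS = tuple("ABCDEFGHIJKLMNOPQRSTUVZ")
COG_MULTI_WITH_I = "Multi+I"
COG_MULTI_WITHOUT_I = "Multi-I"
COG_NONE = "No"
COG_CATEGORIES = COG_LETTERS + (COG_MULTI_WITHOUT_I, COG_MULTI_WITH_I, COG_NONE)


# ---------------------------------------------------------------------------
# population size
# ---------------------------------------------------------------------------

def population_size(profiles: pd.DataFrame, mode: str = "relative") -> pd.DataFrame:
    """Relative population size N_i per composite genome.

    ``profiles`` needs columns ``cg_id``, ``l_i`` (CG length in bp) and
    ``c_i`` (reads mapped to the CG).  In ``relative`` mode the
    length-normalized read densities are closed to sum to 1; in
    ``rpkm_like`` mode N_i = 1e9 * c_i / (C * l_i) with C the total
    mappable reads.  The mode is recorded in ``df.attrs["n_i_mode"]``.
    """
    if mode not in ("relative", "rpkm_like"):
        raise ParameterError(f"unknown N_i mode {mode!r}")
    out = profiles.copy()
    l = out["l_i"].to_numpy(dtype=float)
    c = out["c_i"].to_numpy(dtype=float)
    if np.any(l <= 0):
        raise DomainError("every CG length must be positive")
    C = c.sum()
    if C <= 0:
        raise DomainError("zero total mappable reads")
    density = c / l
    if mode == "relative":
        out["N_i"] = density / density.sum()
    else:
        out["N_i"] = 1e9 * c / (C * l)
    out.attrs["n_i_mode"] = mode
    return out


def fpkm(count: float, gene_length: int, total_mapped: int) -> float:
    """Fragments per kilobase of sequence per million mapped fragments."""
    if gene_length <= 0:
        raise DomainError("gene_length must be positive")
    if total_mapped <= 0:
        raise DomainError("total_mapped must be positive")
    return count * 1e9 / (gene_length * total_mapped)


def fpkm_table(counts: pd.DataFrame, total_mapped: int | None = None) -> pd.Series:
    """Vectorized FPKM for a (gene) count table with columns length, count."""
    total = int(counts["count"].sum()) if total_mapped is None else total_mapped
    if total <= 0:
        raise DomainError("total_mapped must be positive")
    return counts["count"] * 1e9 / (counts["length"] * total)


# ---------------------------------------------------------------------------
# expression calling
# ---------------------------------------------------------------------------

def call_expressed(metat_fpkm: float | np.ndarray, n_i: float | np.ndarray,
                   factor: float = 50.0):
    """Population-normalized expression call.

    A gene is expressed iff its metatranscriptomic FPKM >= factor * N_i of
    its composite genome; boundary equality counts as expressed.
    """
    return np.asarray(metat_fpkm) >= factor * np.asarray(n_i)


@dataclass
class ExpressionRecord:
    gene_id: str
    cg_id: str
    length: int
    metag_fpkm: float
    metat_fpkm: float
    expressed: bool
    threshold_factor: float = 50.0


def expression_table(genes: pd.DataFrame, metat_counts: pd.DataFrame,
                     n_i: pd.Series, factor: float = 50.0,
                     metag_fpkm: pd.Series | None = None) -> pd.DataFrame:
    """Per-gene expression calls for a whole community.

    ``genes`` needs gene_id, cg_id and length_nt; ``metat_counts`` needs
    gene_id, length, count; ``n_i`` maps cg_id -> N_i.  Genes of CGs
    without an N_i (e.g. unbinned contigs) are dropped with a warning
    column rather than called.
    """
    df = genes.merge(metat_counts[["gene_id", "count"]], on="gene_id", how="left")
    df["count"] = df["count"].fillna(0)
    total = int(metat_counts["count"].sum())
    df["metat_fpkm"] = [fpkm(c, l, total) for c, l in zip(df["count"], df["length_nt"])]
    df["n_i"] = df["cg_id"].map(n_i)
    df = df[df["n_i"].notna()].copy()
    df["expressed"] = call_expressed(df["metat_fpkm"].to_numpy(),
                                     df["n_i"].to_numpy(), factor=factor)
    df["threshold_factor"] = factor
    if metag_fpkm is not None:
        df["metag_fpkm"] = df["gene_id"].map(metag_fpkm)
    return df


def expressed_fraction(calls: pd.Series | np.ndarray) -> float:
    """Percentage of genes called expressed (0-100)."""
    calls = np.asarray(calls, dtype=bool)
    if calls.size == 0:
        raise DomainError("composite genome has zero genes")
    return 100.0 * calls.sum() / calls.size


# ---------------------------------------------------------------------------
# functional profile and completeness
# ---------------------------------------------------------------------------

def collapse_cog(categories: str | None) -> str:
    """Collapse a gene's COG letter set to one category.

    Single letters map to themselves; multi-letter sets collapse to
    ``Multi+I`` when lipid metabolism (I) is among them, else ``Multi-I``;
    missing/empty input maps to ``No``.
    """
    if categories is None or (isinstance(categories, float) and np.isnan(categories)) \
            or categories == "":
        return COG_NONE
    letters = [c for c in str(categories) if not c.isspace()]
    for c in letters:
        if c not in COG_LETTERS:
            raise InputError(f"unknown COG category symbol {c!r}")
    if len(letters) == 1:
        return letters[0]
    return COG_MULTI_WITH_I if "I" in letters else COG_MULTI_WITHOUT_I


def cog_profile(gene_categories: pd.Series) -> pd.DataFrame:
    """Category counts and per-CG normalized fractions.

    ``gene_categories`` holds one (possibly multi-letter or empty) COG
    string per gene of a single CG; fractions are counts over the total
    number of genes and sum to 1.
    """
    collapsed = gene_categories.map(collapse_cog)
    counts = collapsed.value_counts().reindex(COG_CATEGORIES, fill_value=0)
    total = counts.sum()
    if total == 0:
        raise DomainError("no genes supplied")
    return pd.DataFrame({"count": counts, "fraction": counts / total})


def completeness(present_markers: set[str] | list[str],
                 uscg_panel: list[str]) -> float:
    """Genome completeness as the percentage of a universal single-copy
    marker panel (40 genes by default) detected at least once."""
    panel = list(dict.fromkeys(uscg_panel))
    if not panel:
        raise ParameterError("empty marker panel")
    present = set(present_markers)
    return 100.0 * sum(1 for m in panel if m in present) / len(panel)


# ---------------------------------------------------------------------------
# amino-acid identity
# ---------------------------------------------------------------------------

@dataclass
class AaiResult:
    n_orthologs: int
    median_identity: float
    sd_identity: float
    identities: np.ndarray | None = None
    empty: bool = False


def _make_aligner(gap_open: float = -11.0, gap_extend: float = -1.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def _identity(alignment) -> float:
    counts = alignment.counts()
    return 100.0 * counts.identities / alignment.length


def aai(proteome_a: dict[str, str], proteome_b: dict[str, str],
        gap_open: float = -11.0, gap_extend: float = -1.0) -> AaiResult:
    """Average amino-acid identity from reciprocal best hits.

    Orthologue pairs are reciprocal best hits under global alignment with
    BLOSUM62; identity of a pair is matches over alignment columns.  The
    result reports median, s.d. and the number of pairs.
    """
    if not proteome_a or not proteome_b:
        raise DomainError("both proteomes must be non-empty")
    aligner = _make_aligner(gap_open, gap_extend)
    ids_a = sorted(proteome_a)
    ids_b = sorted(proteome_b)

    def best_hits(src_ids, src, dst_ids, dst):
        hits, scores = {}, {}
        for qa in src_ids:
            best, best_score = None, -np.inf
            for qb in dst_ids:
                score = aligner.score(src[qa], dst[qb])
                if score > best_score:
                    best, best_score = qb, score
            hits[qa] = best
            scores[qa] = best_score
        return hits

    fwd = best_hits(ids_a, proteome_a, ids_b, proteome_b)
    rev = best_hits(ids_b, proteome_b, ids_a, proteome_a)
    pairs = [(a, b) for a, b in fwd.items() if rev.get(b) == a]
    if not pairs:
        return AaiResult(0, float("nan"), float("nan"), empty=True)
    idents = np.array([
        _identity(aligner.align(proteome_a[a], proteome_b[b])[0]) for a, b in pairs
    ])
    return AaiResult(len(pairs), float(np.median(idents)),
                     float(np.std(idents)), identities=idents)
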