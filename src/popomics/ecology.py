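"""Community ecology layer: rarefied diversity/evenness, lipid
accumulation ratios and taxon-lipid rank correlations.

Diversity is computed on rarefied counts: each sample is repeatedly
subsampled without replacement to a common depth (classical
rarefaction; 6,359 reads and 10 replicates at the package defaults) and
the Gini-Simpson index 1 - sum(p^2) and Pielou evenness
(-sum p ln p) / ln S are averaged over replicates.  Lipid accumulation
is the intracellular/extracellular concentration ratio per compound,
and taxon-lipid association uses Spearman rank correlation with
average-tie ranks.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, ParameterError

logger = logging.getLogger(__name__)


def rarefy(counts: np.ndarray, depth: int = 6359, reps: int = 10,
           seed: int = 0, on_shallow: str = "skip") -> list[np.ndarray] | None:
    """Subsample a count vector without replacement, ``reps`` times.

    Every replicate sums exactly to ``depth``.  A sample shallower than
    the depth is skipped with a warning (returns None) or raises, per
    ``on_shallow`` ("skip" | "error").
    """
    counts = np.asarray(counts, dtype=np.int64)
    if np.any(counts < 0):
        raise DomainError("counts must be non-negative")
    total = int(counts.sum())
    if total < depth:
        if on_shallow == "error":
            raise DomainError(f"sample has {total} reads < depth {depth}")
        logger.warning("sample with %d reads is shallower than depth %d; skipped",
                       total, depth)
        return None
    rng = np.random.default_rng(seed)
    return [rng.multivariate_hypergeometric(counts, depth) for _ in range(reps)]


def simpson_index(proportions: np.ndarray, form: str = "gini") -> float:
    """Simpson diversity.

    ``gini`` (default): 1 - sum(p^2); ``complement_inverse``: 1/sum(p^2);
    ``dominance``: sum(p^2).  The form in use should be recorded alongside
    any reported value.
    """
    p = np.asarray(proportions, dtype=float)
    if p.size == 0:
        raise DomainError("empty proportion vector")
    if abs(p.sum() - 1.0) > 1e-9:
        raise DomainError("proportions must sum to 1")
    d = float(np.sum(p ** 2))
    if form == "gini":
        return 1.0 - d
    if form == "dominance":
        return d
    if form == "complement_inverse":
        return 1.0 / d
    raise ParameterError(f"unknown Simpson form {form!r}")


def pielou_evenness(proportions: np.ndarray) -> float:
    """Pielou evenness J = H / ln S over the S taxa with non-zero
    proportion; undefined (NaN) when only one taxon is present."""
    p = np.asarray(proportions, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise DomainError("proportions must sum to 1")
    nz = p[p > 0]
    s = nz.size
    if s < 2:
        logger.warning("evenness undefined for a single-taxon sample")
        return float("nan")
    h = -float(np.sum(nz * np.log(nz)))
    return h / np.log(s)


def diversity_table(abundance: pd.DataFrame, depth: int = 6359, reps: int = 10,
                    seed: int = 0, simpson_form: str = "gini") -> pd.DataFrame:
    """Rarefied diversity and evenness per sample (taxa x samples counts).

    Each sample is rarefied ``reps`` times and the indices are reported as
    mean +/- s.d. over replicates; shallow samples are skipped.
    """
    ss = np.random.SeedSequence(seed).spawn(abundance.shape[1])
    rows = []
    for j, sample in enumerate(abundance.columns):
        reps_counts = rarefy(abundance[sample].to_numpy(), depth=depth, reps=reps,
                             seed=ss[j].generate_state(1)[0] % (2 ** 31))
        if reps_counts is None:
            continue
        simps, piels = [], []
        for r in reps_counts:
            p = r / r.sum()
            simps.append(simpson_index(p, form=simpson_form))
            piels.append(pielou_evenness(p))
        rows.append((sample, float(np.mean(simps)), float(np.std(simps)),
                     float(np.nanmean(piels)), float(np.nanstd(piels))))
    out = pd.DataFrame(rows, columns=["sample", "simpson_mean", "simpson_sd",
                                      "pielou_mean", "pielou_sd"])
    out.attrs["simpson_form"] = simpson_form
    out.attrs["rarefaction_depth"] = depth
    return out


def accumulation_ratio(lipids: pd.DataFrame) -> pd.DataFrame:
    """Intracellular/extracellular concentration ratio per (compound,
    sample); NaN with a warning where the extracellular value is zero."""
    out = lipids.copy()
    extra = out["extracellular"].to_numpy(dtype=float)
    intra = out["intracellular"].to_numpy(dtype=float)
    if np.any(extra < 0) or np.any(intra < 0):
        raise DomainError("concentrations must be >= 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(extra > 0, intra / extra, np.nan)
    n_undef = int(np.sum(extra == 0))
    if n_undef:
        logger.warning("%d accumulation ratios undefined (extracellular = 0)", n_undef)
    out["ratio"] = ratio
    return out


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation (average ranks for ties).

    NaN with a warning when either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ParameterError("vectors must have equal length")
    if x.size < 3:
        raise ParameterError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        logger.warning("Spearman undefined for a constant vector")
        return float("nan")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)
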