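"""Label-free protein quantification via the normalized spectral index.

The spectral index of a protein sums the fragment-ion intensities over
all its identified peptides and their spectra, so peptide count and
spectral count enter as summation multiplicities.  The normalized
spectral index (NSI) divides by the protein length (removing the bias
against short proteins inherent to raw spectral counts) and by the total
spectral index of the run, which makes the closure identity

    sum_p  NSI_p * length_p  =  1

hold on every run.  Undetected proteins receive no NSI (absence, not
zero); log2 NSI is reported for cross-protein ratio comparisons.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DomainError, InputError


def spectral_index(evidence: pd.DataFrame) -> float:
    """Raw spectral index of one protein: the sum of intensity over all
    (peptide, spectrum) rows of its evidence."""
    if len(evidence) == 0:
        raise DomainError("no evidence: protein is not quantified")
    if (evidence["intensity"] <= 0).any():
        raise InputError("spectrum intensities must be > 0")
    return float(evidence["intensity"].sum())


def nsi_table(evidence: pd.DataFrame) -> pd.DataFrame:
    """NSI records for every detected protein.

    ``evidence`` needs columns protein_id, length_aa, peptide_id,
    spectrum_id, intensity (one row per spectrum).  Returns protein_id,
    length_aa, si_raw, nsi, log2_nsi with
    ``nsi_p = si_p / (length_p * sum_q si_q)``.
    """
    if len(evidence) == 0:
        raise DomainError("empty evidence table")
    if (evidence["intensity"] <= 0).any():
        raise InputError("spectrum intensities must be > 0")
    lengths = evidence.groupby("protein_id")["length_aa"].first()
    if (lengths <= 0).any():
        raise InputError("protein lengths must be > 0")
    si = evidence.groupby("protein_id")["intensity"].sum()
    total = si.sum()
    if total <= 0:
        raise DomainError("zero total intensity")
    nsi = si / (lengths * total)
    out = pd.DataFrame({
        "protein_id": si.index,
        "length_aa": lengths.loc[si.index].to_numpy(),
        "si_raw": si.to_numpy(),
        "nsi": nsi.to_numpy(),
        "log2_nsi": np.log2(nsi.to_numpy()),
    }).reset_index(drop=True)
    return out
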