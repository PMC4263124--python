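import pytest
from hypothesis import settings

import popomics as pm
from popomics import population as pop

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_bundle():
    """The package's default five-population community (seed 1), shared by
    the recovery tests so the expensive generation runs once."""
    return pm.generate_community(pm.default_community(seed=1))


@pytest.fixture(scope="session")
def small_two_pop_bundle():
    """A small, fast two-population community for unit-level checks."""
    spec = pm.two_population_community(
        seed=3, genome_length=150_000,
        total_metag_reads=100_000, total_metat_reads=100_000)
    return pm.generate_community(spec)


def truth_profiles(bundle):
    """Per-population profile table (l_i, c_i, N_i) computed on the
    ground-truth contig->population grouping."""
    prof = (bundle.contigs.groupby("pop_id").agg(l_i=("length", "sum"))
            .reset_index().rename(columns={"pop_id": "cg_id"}))
    c = (bundle.metag_counts
         .merge(bundle.contigs[["contig_id", "pop_id"]], on="contig_id")
         .groupby("pop_id")["count"].sum())
    prof["c_i"] = c.loc[prof["cg_id"]].to_numpy()
    return pop.population_size(prof)


def truth_variant_keys(bundle):
    from popomics.variants import VariantKey

    return {
        VariantKey(r.contig, int(r.pos), r.ref, r.alt)
        for r in bundle.truth.variant_truth.itertuples()
    }
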