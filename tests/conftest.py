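import numpy as np
import pandas as pd
import pytest

from nambin.io_formats import GenotypeMatrix


@pytest.fixture
def toy_matrix():
    """2 lines x 3 sites with one missing call."""
    sites = pd.DataFrame({
        "chrom": ["chr1"] * 3, "pos": [100, 200, 300],
        "allele_a": ["A", "C", "G"], "allele_b": ["G", "T", "A"]})
    calls = np.array([[0, 1, -1], [1, 0, 2]], dtype=np.int8)
    return GenotypeMatrix(lines=["l1", "l2"],
                          family_of={"l1": "famA", "l2": "famA"},
                          sites=sites, calls=calls)


def random_matrix(rng, n_lines=6, n_sites=12, n_families=2):
    sites = pd.DataFrame({
        "chrom": ["chr1"] * n_sites,
        "pos": np.sort(rng.choice(10_000, size=n_sites, replace=False)) + 1,
        "allele_a": rng.choice(list("ACGT"), size=n_sites),
        "allele_b": rng.choice(list("ACGT"), size=n_sites),
    })
    # ensure distinct alleles
    same = sites["allele_a"] == sites["allele_b"]
    sites.loc[same, "allele_b"] = sites.loc[same, "allele_a"].map(
        {"A": "C", "C": "G", "G": "T", "T": "A"})
    lines = [f"l{i}" for i in range(n_lines)]
    family_of = {l: f"fam{i % n_families}" for i, l in enumerate(lines)}
    calls = rng.integers(-1, 3, size=(n_lines, n_sites)).astype(np.int8)
    return GenotypeMatrix(lines=lines, family_of=family_of, sites=sites, calls=calls)
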