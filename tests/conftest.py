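import pytest

from txturnover import ToyConfig, generate_toy_dataset


@pytest.fixture(scope="session")
def toy():
    """Default toy dataset: one planted orthogroup per category, 3 samples,
    zero jitter/divergence, plus one conserved and one low-TPM decoy."""
    return generate_toy_dataset(
        ToyConfig(n_samples=3, n_conserved_decoys=1, n_low_tpm_decoys=1), seed=7)


@pytest.fixture(scope="session")
def toy_dir(toy, tmp_path_factory):
    """The toy dataset written out as GTF/TSV files."""
    d = tmp_path_factory.mktemp("toy")
    paths = toy.write(d)
    return d, paths


def write_gtf(path, rows):
    """rows: (chrom, feature, start1, end1, strand, attrs) in 1-based GTF."""
    with open(path, "w") as fh:
        for chrom, feature, start, end, strand, attrs in rows:
            fh.write("\t".join([chrom, "test", feature, str(start), str(end),
                                ".", strand, ".", attrs]) + "\n")
    return path
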