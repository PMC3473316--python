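import pytest
from hypothesis import HealthCheck, settings

from poolsnv import SimConfig, run_pipeline

settings.register_profile(
    "suite", deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def study_run(tmp_path_factory):
    """One full synthetic experiment at the default study conditions
    (8 pools, 30X, 1% error, 0.5% missing), shared across tests."""
    cfg = SimConfig(seed=1)
    return run_pipeline(cfg, tmp_path_factory.mktemp("study"))


@pytest.fixture()
def tiny_config():
    """A miniature configuration for fast unit-level simulations."""
    return SimConfig(
        seed=5, n_scaffolds=1, scaffold_len=11_000, genes_per_scaffold=3,
        n_variants_per_class={
            "shared_all": 8, "pool_specific": 6, "fixed_differential": 4,
            "background": 4, "near_intron": 4, "clustered": 3, "indel": 4,
        },
    )


def write_sam(path, scaffolds, reads):
    """Minimal SAM writer for hand-built fixtures.

    ``scaffolds``: {name: length}; ``reads``: iterables of
    (qname, flag, rname, pos, mapq, cigar, seq, qual_string).
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for name, ln in scaffolds.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{ln}\n")
        for qname, flag, rname, pos, mapq, cigar, seq, qual in reads:
            fh.write(f"{qname}\t{flag}\t{rname}\t{pos}\t{mapq}\t{cigar}\t"
                     f"*\t0\t0\t{seq}\t{qual}\n")
    return path
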