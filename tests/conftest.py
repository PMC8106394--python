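import pytest
from hypothesis import settings

from kderep.synth import SynthSpec, generate_family_set

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture()
def tiny_fasta(tmp_path):
    path = tmp_path / "tiny.fna"
    path.write_text(">a desc\nAC\nGT\n>b\nTT\n")
    return path


@pytest.fixture(scope="session")
def family_set(tmp_path_factory):
    """A well-separated 10-group x 5-member family set (shared per session)."""
    out = tmp_path_factory.mktemp("family")
    spec = SynthSpec(seed=7)
    records, truth = generate_family_set(spec, out)
    return records, truth


@pytest.fixture(scope="session")
def small_family_set(tmp_path_factory):
    """A faster 4-group x 3-member set for engine-level tests."""
    out = tmp_path_factory.mktemp("family_small")
    spec = SynthSpec(n_groups=4, members_per_group=3, genome_length=20_000, seed=11)
    records, truth = generate_family_set(spec, out)
    return records, truth


def purity(result_groups, truth):
    """1.0 when no final group mixes two true groups (chimeras ignored)."""
    mixed = 0
    for members in result_groups.values():
        labels = {truth.group_of[m] for m in members if m not in truth.chimeras}
        if len(labels) > 1:
            mixed += 1
    return 1.0 - mixed / len(result_groups)
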