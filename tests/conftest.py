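import pytest

from utrscope.synthetic_data import (
    FamilySpec,
    GroupSpec,
    UorfSpec,
    abca1_like_family,
    generate_family,
)


@pytest.fixture(scope="session")
def default_family():
    """One deterministic default ortholog family shared across tests."""
    spec = abca1_like_family(seed=0)
    records, aln, truth = generate_family(spec)
    return spec, records, aln, truth


@pytest.fixture(scope="session")
def clean_family():
    """Mutation- and indel-free family: planted coordinates hold exactly."""
    spec = abca1_like_family(seed=1, sub_rate=0.0, block_sub_rate=0.0, indel_rate=0.0)
    records, aln, truth = generate_family(spec)
    return spec, records, aln, truth


def family20_spec(seed: int) -> FamilySpec:
    """20-species family at the default conservation/divergence settings."""
    head, uorf_len = 6, 90

    def grp(label, n, rel, rng):
        k = rel[1] if rel[0] == "gap" else -rel[1]
        return GroupSpec(label, n, head + uorf_len + k, rng, rel)

    return FamilySpec(
        groups=[
            grp("primates", 6, ("overlap", 22), (280, 320)),
            grp("rodents", 5, ("gap", 1), (180, 260)),
            grp("other_placental", 3, ("gap", 7), (200, 280)),
            grp("marsupials", 2, ("gap", 29), (40, 330)),
            grp("reptiles_birds", 2, ("gap", 16), (30, 140)),
            grp("rayfinned_a", 2, ("gap", 4), (50, 150)),
        ],
        seed=seed,
    )


def block15_spec(seed: int) -> FamilySpec:
    """Family whose conserved block coincides with a 15-nt uORF, surrounded
    by heavily mutated background — isolates the hot-spot run length."""
    return FamilySpec(
        groups=[GroupSpec("other", 20, 22, (80, 120))],
        block_seq="ATGCAACCACAGTGA",
        uorf=UorfSpec(len_nt=15, relation=("gap", 7)),
        gc_targets={"before": 50.0, "after": 50.0},
        sub_rate=0.5,
        block_sub_rate=0.02,
        indel_rate=0.02,
        seed=seed,
    )
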