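import pytest

from myriakit import simulate as sim
from myriakit.types import HairpinAnnotation


@pytest.fixture(scope="session")
def hairpin_set():
    """Ten hairpins, two families duplicated (12 loci)."""
    return sim.make_hairpin_set(10, dup_fraction=0.2, seed=11)


@pytest.fixture(scope="session")
def small_study():
    """Two species x three stages over 20 unique hairpins with planted switches."""
    hairpins, fasta = sim.make_hairpin_set(20, dup_fraction=0.0, seed=5)
    truth = sim.make_arm_truth(hairpins, ["spA", "spB"], switch_fraction=0.15, seed=5)
    noise = sim.ReadNoiseConfig(depth_mean=400, seed=5)
    samples = [
        sim.simulate_sample(hairpins, truth, noise, f"{sp}_{st}", sp, seed=5, stage_label=st)
        for sp in ("spA", "spB")
        for st in sim.DEFAULT_STAGES
    ]
    return hairpins, truth, samples


@pytest.fixture(scope="session")
def genome_fixture():
    cfg = sim.GenomeFixtureConfig()
    return sim.make_genome_fixture(cfg, seed=7), cfg


def make_hairpin(
    mirna_id="mir-x",
    family_id=None,
    hairpin_seq="ACGTACGTACGTACGTACGTTTTTTTTTTTGCATGCATGCATGCATGCAT",
    arm5p=(0, 20),
    arm3p=(30, 50),
    seq_id="chr1",
    strand="+",
    start=1000,
    species_id="spA",
):
    """Hand-built hairpin for targeted unit tests."""
    return HairpinAnnotation(
        mirna_id=mirna_id,
        family_id=family_id or mirna_id,
        species_id=species_id,
        seq_id=seq_id,
        strand=strand,
        hairpin_interval=(start, start + len(hairpin_seq)),
        hairpin_seq=hairpin_seq,
        arm5p=arm5p,
        arm3p=arm3p,
    )
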