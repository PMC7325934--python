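import pytest

from amplicore import read_prep as rp
from amplicore import subotu as so
from amplicore import synthetic_data as sd


@pytest.fixture(scope="session")
def reference20():
    return sd.build_reference(20, seed=7)


@pytest.fixture(scope="session")
def noisy_sim(reference20):
    """12-sample DC-only design, 0.5% substitution error, no chimeras."""
    config = sd.SimulationConfig(
        reads_per_sample=250,
        rng_seed=7,
        substitution_error_rate=0.005,
        chimera_rate=0.0,
        chambers=("DC",),
    )
    truth = sd.simulate_design(reference20, config)
    reads, read_truth = sd.generate_reads(reference20, truth, config)
    return config, truth, reads, read_truth


@pytest.fixture(scope="session")
def prepared_pool(noisy_sim):
    """Prepared reads, per-read retained sequence, and the dereplicated pool."""
    _, _, reads, _ = noisy_sim
    prep_config = rp.PrepConfig()
    per_sample = {}
    read_to_seq = {}
    for sample, sample_reads in reads.items():
        kept = []
        for read_id, seq, qual in sample_reads:
            res = rp.prepare_read(seq, prep_config, quality=qual)
            if res.retained:
                kept.append(res.sequence)
                read_to_seq[read_id] = res.sequence
        per_sample[sample] = kept
    pool = so.dereplicate(per_sample)
    return per_sample, read_to_seq, pool


@pytest.fixture(scope="session")
def clustered(prepared_pool):
    per_sample, read_to_seq, pool = prepared_pool
    config = so.ClusterConfig()
    seeds = so.designate_seeds(pool, config)
    table = so.cluster_to_features(pool, seeds, config)
    return pool, seeds, table
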