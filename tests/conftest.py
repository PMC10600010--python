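import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import admixfreq as af

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """300-sample, 600-variant K=3 admixed cohort with truth."""
    cfg = af.SimulationConfig(n_samples=300, n_variants=600, seed=11)
    freqs = af.gen_ancestral_frequencies(cfg.n_variants, cfg.K, cfg.sfs_params, seed=11)
    haps, lai_truth = af.gen_admixed_haplotypes(cfg, freqs)
    return cfg, freqs, haps, lai_truth


@pytest.fixture(scope="session")
def pedigree_drop():
    """Five 3-generation families gene-dropped with truth IBD and origins."""
    ped = af.three_generation_pedigree(5)
    cfg = af.SimulationConfig(n_samples=len(ped.founders), n_variants=200, seed=7)
    freqs = af.gen_ancestral_frequencies(cfg.n_variants, cfg.K, cfg.sfs_params, seed=7)
    founders, _ = af.gen_admixed_haplotypes(cfg, freqs)
    cohort, ibd, degrees, origins = af.gene_drop_pedigree(
        founders, ped, cfg.genetic_map, seed=7, return_origins=True
    )
    return ped, cfg, cohort, ibd, degrees, origins


def origin_label(breaks: np.ndarray, labels: np.ndarray, pos: int) -> int:
    """Founder-haplotype label of a gene-dropped haplotype at a position."""
    t = np.searchsorted(breaks, pos, side="right") - 1
    return int(labels[min(t, len(labels) - 1)])
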